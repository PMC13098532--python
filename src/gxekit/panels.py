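"""Genotype containers and minimal VCF / tabular I/O.

A :class:`GenotypePanel` holds an individuals x SNPs allele-count matrix
together with the frequency of the counted allele at each SNP.  Counts are
0/1/2 for observed genotypes and may be fractional (expected dosages in
[0, 2]) when a panel was produced by Mendelian imputation.  The counted
allele is, by convention, the allele whose frequency is stored; the simulator
attaches no strand or ref/alt semantics beyond that (the VCF exporter writes
the counted allele as ALT).

A :class:`PedigreeIndex` links children to rows of the parental panels and
partitions them into families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypePanel",
    "PedigreeIndex",
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
]


@dataclass
class GenotypePanel:
    """Allele-count matrix with per-SNP counted-allele frequencies.

    Parameters
    ----------
    values
        ``(n_individuals, n_snps)`` array. Integer entries must lie in
        {0, 1, 2}; fractional entries (imputed dosages) in [0, 2]. ``nan``
        marks missing/masked genotypes.
    allele_freqs
        Frequency of the counted allele at each SNP, strictly inside (0, 1).
    ids
        Individual identifiers, one per row.
    snp_ids
        Variant identifiers, one per column (generated if omitted).
    """

    values: np.ndarray
    allele_freqs: np.ndarray
    ids: np.ndarray | None = None
    snp_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (individuals x SNPs) array")
        if self.values.shape[1] != self.allele_freqs.shape[0]:
            raise ValueError(
                f"{self.values.shape[1]} SNP columns but "
                f"{self.allele_freqs.shape[0]} allele frequencies"
            )
        if np.any((self.allele_freqs <= 0) | (self.allele_freqs >= 1)):
            raise ValueError("allele_freqs must lie strictly in (0, 1)")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("genotype values must lie in [0, 2]")
        if self.ids is None:
            self.ids = np.arange(self.values.shape[0])
        self.ids = np.asarray(self.ids)
        if self.ids.shape[0] != self.values.shape[0]:
            raise ValueError("ids length must match number of rows")
        if self.snp_ids is None:
            self.snp_ids = np.array([f"snp{j}" for j in range(self.n_snps)])
        self.snp_ids = np.asarray(self.snp_ids)
        if self.snp_ids.shape[0] != self.n_snps:
            raise ValueError("snp_ids length must match number of SNP columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def is_integer(self) -> bool:
        """True when every non-missing entry is a hard call in {0, 1, 2}."""
        finite = self.values[np.isfinite(self.values)]
        return bool(np.all(np.isin(finite, (0.0, 1.0, 2.0))))

    def take(self, rows: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            self.values[rows], self.allele_freqs, self.ids[rows], self.snp_ids
        )


@dataclass
class PedigreeIndex:
    """Child -> parent row links plus family membership.

    ``mother_row[i]`` / ``father_row[i]`` index the mother/father panels for
    child ``i``; ``family_id`` partitions children into sibships (siblings
    share both parent rows).
    """

    mother_row: np.ndarray
    father_row: np.ndarray
    family_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mother_row = np.asarray(self.mother_row, dtype=int)
        self.father_row = np.asarray(self.father_row, dtype=int)
        if self.mother_row.shape != self.father_row.shape:
            raise ValueError("mother_row and father_row must have equal length")
        if self.family_id is None:
            # couples are families; one entry per child
            self.family_id = np.arange(self.mother_row.shape[0])
        self.family_id = np.asarray(self.family_id, dtype=int)
        if self.family_id.shape != self.mother_row.shape:
            raise ValueError("family_id length must match number of children")
        # siblings must share both parents
        for fam in np.unique(self.family_id):
            rows = self.family_id == fam
            if np.unique(self.mother_row[rows]).size != 1 or (
                np.unique(self.father_row[rows]).size != 1
            ):
                raise ValueError(f"family {fam} has inconsistent parent links")

    @property
    def n_children(self) -> int:
        return self.mother_row.shape[0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Counted allele frequency">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path: str, panel: GenotypePanel, sample_prefix: str = "ind") -> None:
    """Write hard-call genotypes as a minimal single-chromosome VCF 4.2.

    Only the GT field is emitted; the counted allele is written as ALT so a
    round-trip recovers the allele-count matrix via the ALT dosage.
    Fractional dosages cannot be represented (use :func:`write_dosage_tsv`).
    """
    if not panel.is_integer():
        raise ValueError("VCF GT cannot carry fractional dosages")
    samples = [f"{sample_prefix}{i}" for i in panel.ids]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(panel.n_snps):
            calls = "\t".join(
                gt_map.get(v, "./.") for v in panel.values[:, j]
            )
            info = f"AF={panel.allele_freqs[j]:.6g}"
            fh.write(
                f"1\t{j + 1}\t{panel.snp_ids[j]}\tA\tG\t.\t.\t{info}\tGT\t{calls}\n"
            )


def read_vcf(path: str) -> GenotypePanel:
    """Read a (plain-text) VCF written by :func:`write_vcf` back into a panel."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = vcf.samples
    rows: list[np.ndarray] = []
    freqs: list[float] = []
    snp_ids: list[str] = []
    for variant in vcf:
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(variant.gt_types, dtype=float)
        counts = np.where(gt == 3, 2.0, gt)
        counts[gt == 2] = np.nan
        rows.append(counts)
        af = variant.INFO.get("AF")
        freqs.append(float(af) if af is not None else float(np.nanmean(counts)) / 2)
        snp_ids.append(variant.ID or f"snp{len(snp_ids)}")
    vcf.close()
    values = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return GenotypePanel(
        values,
        np.asarray(freqs),
        ids=np.asarray(samples),
        snp_ids=np.asarray(snp_ids),
    )


def write_dosage_tsv(path: str, panel: GenotypePanel) -> None:
    """Tab-delimited dosage sidecar for fractional (imputed) genotypes."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(map(str, panel.snp_ids)) + "\n")
        for i in range(panel.n):
            row = "\t".join(f"{v:.6g}" for v in panel.values[i])
            fh.write(f"{panel.ids[i]}\t{row}\n")
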