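"""Data model and readers/writers for genotype matrices, sample metadata and alignments.

The central container is :class:`GenotypeMatrix`: a sites x samples matrix of
alternate-allele dosages with an explicit missingness mask and per-sample ploidy
(diploid females, haploid males). Genotypes travel as VCF, sample metadata as a
tab-separated table, and mitochondrial sequences as aligned FASTA.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

__all__ = [
    "GenotypeMatrix",
    "SequenceAlignment",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_metadata",
    "write_metadata",
    "read_fasta_alignment",
    "write_fasta",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ["sample_id", "group", "sex", "region", "distance_class", "read_count"]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be interpreted as a biallelic SNP genotype matrix."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a panel of mixed-ploidy samples.

    Attributes
    ----------
    chrom, pos, locus
        Per-site coordinates: scaffold name, 1-based position and a locus tag
        (RAD-tag identifier; several SNPs may share one locus).
    dosage
        (n_sites, n_samples) int8 array counting alternate alleles; entries under
        ``missing`` are meaningless and must never be read without the mask.
    missing
        (n_sites, n_samples) boolean mask, True where no call was made.
    samples
        Sample identifiers, order matches dosage columns.
    ploidy
        Per-sample ploidy (1 for haploid males, 2 for diploid females).
    coverage
        Optional per-site mean depth (x units).
    """

    chrom: np.ndarray
    pos: np.ndarray
    locus: np.ndarray
    dosage: np.ndarray
    missing: np.ndarray
    samples: list
    ploidy: np.ndarray
    coverage: np.ndarray | None = None
    skipped_records: int = field(default=0, compare=False)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.locus = np.asarray(self.locus, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.samples = list(self.samples)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        if self.coverage is not None:
            self.coverage = np.asarray(self.coverage, dtype=float)
        self._validate()

    def _validate(self):
        n_sites, n_samples = self.dosage.shape
        if self.missing.shape != (n_sites, n_samples):
            raise ValueError("missing mask shape does not match dosage")
        if len(self.samples) != n_samples or len(self.ploidy) != n_samples:
            raise ValueError("sample metadata length does not match dosage columns")
        if len(self.chrom) != n_sites or len(self.pos) != n_sites or len(self.locus) != n_sites:
            raise ValueError("site annotation length does not match dosage rows")
        if len(set(self.samples)) != n_samples:
            raise ValueError("duplicate sample ids")
        if np.any(self.pos < 0):
            raise ValueError("negative positions")
        if not np.all(np.isin(self.ploidy, (1, 2))):
            raise ValueError("ploidy must be 1 or 2")
        called = ~self.missing
        if np.any(called & ((self.dosage < 0) | (self.dosage > self.ploidy[None, :]))):
            raise ValueError("dosage outside 0..ploidy for a called genotype")
        ids = list(zip(self.chrom, self.pos, self.locus))
        if len(set(ids)) != n_sites:
            raise ValueError("site ids (chrom, pos, locus) not unique")

    # -- basic geometry -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def site_order(self) -> np.ndarray:
        """Indices sorting sites by (chrom ascending, pos ascending)."""
        return np.lexsort((self.pos, self.chrom.astype(str)))

    def sort_sites(self) -> "GenotypeMatrix":
        return self.take_sites(self.site_order())

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            locus=self.locus[idx],
            dosage=self.dosage[idx],
            missing=self.missing[idx],
            coverage=None if self.coverage is None else self.coverage[idx],
        )

    def take_samples(self, names) -> "GenotypeMatrix":
        index = {s: j for j, s in enumerate(self.samples)}
        cols = np.array([index[n] for n in names], dtype=int)
        return replace(
            self,
            dosage=self.dosage[:, cols],
            missing=self.missing[:, cols],
            samples=[self.samples[j] for j in cols],
            ploidy=self.ploidy[cols],
        )

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        same_cov = (self.coverage is None) == (other.coverage is None) and (
            self.coverage is None or np.allclose(self.coverage, other.coverage)
        )
        called = ~self.missing
        return (
            list(self.chrom) == list(other.chrom)
            and np.array_equal(self.pos, other.pos)
            and list(self.locus) == list(other.locus)
            and self.samples == other.samples
            and np.array_equal(self.ploidy, other.ploidy)
            and np.array_equal(self.missing, other.missing)
            and np.array_equal(self.dosage[called], other.dosage[~other.missing])
            and same_cov
        )


@dataclass
class SequenceAlignment:
    """Equal-length aligned nucleotide sequences keyed by sample id."""

    ids: list
    seqs: list

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences of unequal length: {sorted(lengths)}; align upstream")
        self.seqs = [s.upper() for s in self.seqs]

    def __len__(self):
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped and counted in
    ``skipped_records``. Per-sample ploidy is inferred from the GT field and must
    be consistent across sites; a sample whose GT length changes between records
    raises :class:`VcfParseError`. Sites are sorted by (chrom, pos) — the
    deterministic order jackknife blocks rely on. Mean depth is taken from the
    INFO ``DP`` field when present (DP / n_samples).
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except Exception as exc:  # pragma: no cover - pysam error text varies
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    has_dp = "DP" in vf.header.info
    n = len(samples)
    ploidy = np.zeros(n, dtype=np.int8)
    chrom, pos, locus, cov = [], [], [], []
    dosage_rows, missing_rows = [], []
    skipped = 0
    any_cov = False
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or rec.ref is None or len(rec.ref) != 1 or len(alts[0]) != 1 \
                or rec.ref not in "ACGT" or alts[0] not in "ACGT":
            skipped += 1
            continue
        dos = np.zeros(n, dtype=np.int8)
        miss = np.zeros(n, dtype=bool)
        for j, s in enumerate(samples):
            gt = rec.samples[s].get("GT", (None,))
            alleles = [a for a in gt if a is not None]
            if not alleles and all(a is None for a in gt):
                miss[j] = True
                continue
            if len(alleles) != len(gt):
                raise VcfParseError(
                    f"partial genotype call for sample {s} at {rec.chrom}:{rec.pos}"
                )
            if ploidy[j] == 0:
                ploidy[j] = len(gt)
            elif ploidy[j] != len(gt):
                raise VcfParseError(
                    f"mixed ploidy for sample {s}: {ploidy[j]} then {len(gt)} "
                    f"at {rec.chrom}:{rec.pos}"
                )
            if any(a not in (0, 1) for a in alleles):
                raise VcfParseError(
                    f"non-biallelic allele index for sample {s} at {rec.chrom}:{rec.pos}"
                )
            dos[j] = sum(alleles)
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        locus.append(rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}")
        dp = rec.info.get("DP") if has_dp else None
        if dp is not None:
            any_cov = True
            cov.append(float(dp) / max(n, 1))
        else:
            cov.append(np.nan)
        dosage_rows.append(dos)
        missing_rows.append(miss)
    vf.close()
    if not dosage_rows:
        dosage = np.zeros((0, n), dtype=np.int8)
        missing = np.zeros((0, n), dtype=bool)
    else:
        dosage = np.vstack(dosage_rows)
        missing = np.vstack(missing_rows)
    # samples never called anywhere: assume diploid (cannot infer)
    ploidy[ploidy == 0] = 2
    geno = GenotypeMatrix(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        locus=np.array(locus, dtype=object),
        dosage=dosage,
        missing=missing,
        samples=samples,
        ploidy=ploidy,
        coverage=np.array(cov) if any_cov else None,
        skipped_records=skipped,
    )
    return geno.sort_sites()


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(geno: GenotypeMatrix, path, metadata: pd.DataFrame | None = None) -> None:
    """Write a genotype matrix as a genotypes-only VCFv4.2 file.

    Haploid samples get single-allele GT fields ("0", "1" or "."); diploid
    samples get unphased "a/b" fields. Round-trips through :func:`read_vcf`
    at the dosage/missingness/ploidy level. REF/ALT are fixed to A/C: the
    matrix stores dosages, not nucleotides.
    """
    order = geno.site_order()
    contigs = []
    for c in geno.chrom[order]:
        if not contigs or contigs[-1] != c:
            contigs.append(c)
    buf = _io.StringIO()
    buf.write(_VCF_HEADER)
    for c in dict.fromkeys(contigs):
        buf.write(f"##contig=<ID={c}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(geno.samples) + "\n")
    n = geno.n_samples
    for i in order:
        info = "."
        if geno.coverage is not None and np.isfinite(geno.coverage[i]):
            info = f"DP={int(round(geno.coverage[i] * n))}"
        fields = [
            str(geno.chrom[i]), str(geno.pos[i]), str(geno.locus[i]),
            "A", "C", ".", "PASS", info, "GT",
        ]
        for j in range(n):
            if geno.missing[i, j]:
                gt = "." if geno.ploidy[j] == 1 else "./."
            elif geno.ploidy[j] == 1:
                gt = str(int(geno.dosage[i, j]))
            else:
                d = int(geno.dosage[i, j])
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[d]
            fields.append(gt)
        buf.write("\t".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

KNOWN_GROUPS = {"CH", "NNear", "NFar", "SNear", "SFar", "outgroup"}


def read_metadata(path) -> pd.DataFrame:
    """Read the tab-separated sample table.

    Requires columns ``sample_id group sex region distance_class read_count``.
    Unknown group labels are allowed but flagged in the ``known_group`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).apply(
        lambda s: s.str.strip() if s.dtype == object else s
    )
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"metadata missing required column(s): {missing_cols}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s): {dups}")
    if (df["group"].fillna("") == "").any():
        raise ValueError("empty group label")
    df["read_count"] = df["read_count"].astype(np.int64)
    if (df["read_count"] < 0).any():
        raise ValueError("negative read_count")
    df["known_group"] = df["group"].isin(KNOWN_GROUPS)
    return df.reset_index(drop=True)


def write_metadata(df: pd.DataFrame, path) -> None:
    df[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def group_map(metadata: pd.DataFrame) -> dict:
    """sample_id -> group label."""
    return dict(zip(metadata["sample_id"], metadata["group"]))


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------


def read_fasta_alignment(path) -> SequenceAlignment:
    """Read a pre-aligned FASTA; unequal sequence lengths are an error."""
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SequenceAlignment(
        ids=[r.id for r in records], seqs=[str(r.seq) for r in records]
    )


def write_fasta(aln: SequenceAlignment, path) -> None:
    with open(path, "w") as fh:
        for i, s in zip(aln.ids, aln.seqs):
            fh.write(f">{i}\n")
            for k in range(0, len(s), 80):
                fh.write(s[k : k + 80] + "\n")
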