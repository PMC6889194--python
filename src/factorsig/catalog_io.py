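"""Read somatic mutation tables, extract flanking context, and build catalogs.

Mutations are encoded pyrimidine-centrically: a substitution whose reference
base is a purine is reverse-complemented (flanks included, transcription
strand flipped) so that every feature has a C or T reference base.  A feature
is the tuple (substitution type, four flanking bases at positions -2/-1/+1/+2,
optional transcription strand), giving 6 * 4**4 * 2 = 3072 combinations with
strand and 1536 without.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES: tuple[str, ...] = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
SUB_TYPES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
STRANDS: tuple[str, ...] = ("+", "-")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: factor positions of the five-base model, in canonical order
POSITIONS_STRAND: tuple[str, ...] = (
    "sub_type", "flank_m2", "flank_m1", "flank_p1", "flank_p2", "strand",
)
POSITIONS_NOSTRAND: tuple[str, ...] = POSITIONS_STRAND[:-1]

POSITION_CATEGORIES: dict[str, tuple[str, ...]] = {
    "sub_type": SUB_TYPES,
    "flank_m2": BASES,
    "flank_m1": BASES,
    "flank_p1": BASES,
    "flank_p2": BASES,
    "strand": STRANDS,
}

#: default chromosome restriction: autosomes 1-22, with or without "chr"
AUTOSOMES: frozenset[str] = frozenset(
    [str(i) for i in range(1, 23)] + [f"chr{i}" for i in range(1, 23)]
)


class ContextUnavailable(Exception):
    """Flanking context cannot be determined; the mutation is excluded."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def positions_for(includes_strand: bool) -> tuple[str, ...]:
    return POSITIONS_STRAND if includes_strand else POSITIONS_NOSTRAND


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass
class MutationRecord:
    """A single-base somatic substitution call, as read from the input."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vaf: float | None = None
    tx_strand: str | None = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.tx_strand is not None and self.tx_strand not in STRANDS:
            raise ValueError(f"tx_strand must be + or -, got {self.tx_strand!r}")


@dataclass(frozen=True)
class MutationFeature:
    """Pyrimidine-centric factorized mutation feature.

    ``flank_m2`` .. ``flank_p2`` are the reference bases at positions
    -2, -1, +1, +2 relative to the substituted base after pyrimidine
    normalization; ``strand`` is the transcription strand of the pyrimidine
    (``None`` when unknown).
    """

    sub_type: str
    flank_m2: str
    flank_m1: str
    flank_p1: str
    flank_p2: str
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.sub_type not in SUB_TYPES:
            raise ValueError(f"bad sub_type {self.sub_type!r}")
        for b in (self.flank_m2, self.flank_m1, self.flank_p1, self.flank_p2):
            if b not in BASES:
                raise ValueError(f"bad flank base {b!r}")
        if self.strand is not None and self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def category(self, position: str) -> str:
        value = getattr(self, position if position != "strand" else "strand")
        if value is None:
            raise ValueError("feature has no strand")
        return value

    def indices(self, includes_strand: bool) -> tuple[int, ...]:
        """Category index at each factor position, in canonical order."""
        return tuple(
            POSITION_CATEGORIES[p].index(self.category(p))
            for p in positions_for(includes_strand)
        )


def all_features(includes_strand: bool) -> list[MutationFeature]:
    """Enumerate every encodable feature combination in canonical order."""
    pos = positions_for(includes_strand)
    combos = itertools.product(*(POSITION_CATEGORIES[p] for p in pos))
    out = []
    for combo in combos:
        kwargs = dict(zip(pos, combo))
        out.append(MutationFeature(**kwargs))
    return out


# ---------------------------------------------------------------------------
# Readers


def _maf_records(path: Path) -> tuple[list[MutationRecord], int]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MAF-like table missing columns: {sorted(missing)}")
    records, skipped = [], 0
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES or ref == alt:
            skipped += 1
            continue
        vaf = getattr(row, "vaf", None)
        vaf = float(vaf) if vaf is not None and not pd.isna(vaf) else None
        strand = getattr(row, "strand", None)
        strand = str(strand) if strand is not None and not pd.isna(strand) else None
        records.append(
            MutationRecord(
                sample_id=str(row.sample), chrom=str(row.chrom), pos=int(row.pos),
                ref=ref, alt=alt, vaf=vaf, tx_strand=strand,
            )
        )
    return records, skipped


def _vcf_records(path: Path) -> tuple[list[MutationRecord], int]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample = vcf.samples[0] if vcf.samples else Path(path).stem
    records, skipped = [], 0
    for variant in vcf:
        ref = variant.REF.upper()
        for alt in variant.ALT:  # multi-allelic rows are split
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                skipped += 1
                continue
            vaf = None
            try:
                af = variant.INFO.get("AF")
                if af is not None:
                    vaf = float(af[0] if isinstance(af, tuple) else af)
            except Exception:
                vaf = None
            records.append(
                MutationRecord(
                    sample_id=sample, chrom=variant.CHROM, pos=variant.POS,
                    ref=ref, alt=alt, vaf=vaf,
                )
            )
    return records, skipped


def read_mutations(path: str | Path, dialect: str = "maf_like") -> list[MutationRecord]:
    """Read single-base substitutions from a mutation table.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"maf_like"`` — tab-delimited with columns ``sample, chrom, pos,
        ref, alt`` and optional ``vaf, strand, purity``; or ``"vcf"``.

    Non-SNV rows (indels, symbolic alleles) are skipped; the skip count is
    logged at INFO level.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "maf_like":
        records, skipped = _maf_records(path)
    elif dialect == "vcf":
        records, skipped = _vcf_records(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if skipped:
        logger.info("skipped %d non-SNV rows in %s", skipped, path)
    return records


def read_sample_meta(path: str | Path) -> dict[str, dict]:
    """Extract per-sample metadata (purity, subtype, group) from a MAF-like table."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    meta: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        entry = meta.setdefault(str(row.sample), {})
        for key in ("purity", "subtype", "group"):
            val = getattr(row, key, None)
            if val is not None and not pd.isna(val):
                entry[key] = float(val) if key == "purity" else str(val)
    return meta


# ---------------------------------------------------------------------------
# Context extraction and feature encoding


def _lookup_chrom(reference, chrom: str):
    for name in (chrom, f"chr{chrom}", chrom.removeprefix("chr")):
        if name in reference:
            return reference[name]
    raise KeyError(f"chromosome {chrom!r} not in reference")


def extract_context(record: MutationRecord, reference) -> str:
    """Reference bases at positions ``pos-2 .. pos+2`` (5 characters, upper).

    ``reference`` is a mapping from chromosome name to sequence supporting
    slicing (e.g. a :class:`pyfaidx.Fasta`).  Raises :class:`KeyError` if the
    chromosome is absent and :class:`ContextUnavailable` if the window runs
    off the chromosome, contains a non-ACGT base, or its middle base
    disagrees with ``record.ref``.
    """
    seq = _lookup_chrom(reference, record.chrom)
    if record.pos - 2 < 1 or record.pos + 2 > len(seq):
        raise ContextUnavailable("context_window")
    window = str(seq[record.pos - 3 : record.pos + 2]).upper()
    if any(b not in BASES for b in window):
        raise ContextUnavailable("context_N")
    if window[2] != record.ref:
        raise ContextUnavailable("ref_mismatch")
    return window


def encode_feature(
    context: str, ref: str, alt: str, tx_strand: str | None = None
) -> MutationFeature:
    """Encode a substitution and its 5-base context as a pyrimidine-centric feature.

    If ``ref`` is a purine the substitution, flanks and strand are
    reverse-complemented so the encoded reference base is C or T.
    """
    context = context.upper()
    ref, alt = ref.upper(), alt.upper()
    if len(context) != 5 or any(b not in BASES for b in context):
        raise ValueError(f"context must be 5 ACGT bases, got {context!r}")
    if context[2] != ref:
        raise ValueError("context middle base does not match ref")
    if alt not in BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref not in PYRIMIDINES:
        context = reverse_complement(context)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        if tx_strand is not None:
            tx_strand = "-" if tx_strand == "+" else "+"
    return MutationFeature(
        sub_type=f"{ref}>{alt}",
        flank_m2=context[0],
        flank_m1=context[1],
        flank_p1=context[3],
        flank_p2=context[4],
        strand=tx_strand,
    )


# ---------------------------------------------------------------------------
# Catalog


@dataclass
class MutationCatalog:
    """Per-sample counts over unique mutation features.

    ``counts[i, j]`` is the number of mutations of sample ``samples[i]``
    with feature ``features[j]``.
    """

    samples: list[str]
    features: list[MutationFeature]
    counts: np.ndarray  # (n_samples, n_features) int64
    includes_strand: bool
    sample_meta: dict[str, dict] = field(default_factory=dict)
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.samples), len(self.features)):
            raise ValueError("counts shape does not match samples x features")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_mutations(self) -> int:
        return int(self.counts.sum())

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def feature_index_matrix(self) -> np.ndarray:
        """(n_features, n_positions) category-index matrix in canonical order."""
        return np.array(
            [f.indices(self.includes_strand) for f in self.features], dtype=np.int64
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MutationCatalog":
        idx = [self.samples.index(s) for s in sample_ids]
        return MutationCatalog(
            samples=list(sample_ids),
            features=list(self.features),
            counts=self.counts[idx],
            includes_strand=self.includes_strand,
            sample_meta={s: self.sample_meta.get(s, {}) for s in sample_ids},
        )


def build_catalog(
    records: Iterable[MutationRecord],
    reference,
    keep_chroms: frozenset[str] | set[str] | None = None,
    sample_meta: Mapping[str, Mapping] | None = None,
    include_strand: bool | None = None,
) -> MutationCatalog:
    """Aggregate mutation records into a catalog of per-sample feature counts.

    Records outside ``keep_chroms`` (default: autosomes 1-22) are dropped, as
    are records whose 5-base context is unavailable.  The strand factor is
    included only when every retained record carries a transcription strand
    (``include_strand=None`` selects this automatically).
    """
    records = list(records)
    if not records:
        raise ValueError("no input records")
    if keep_chroms is None:
        keep_chroms = AUTOSOMES
    drops: Counter[str] = Counter()
    encoded: list[tuple[str, MutationFeature]] = []
    kept_strand: list[str | None] = []
    for rec in records:
        if rec.chrom not in keep_chroms:
            drops["chromosome"] += 1
            continue
        try:
            context = extract_context(rec, reference)
        except ContextUnavailable as exc:
            drops[exc.reason] += 1
            continue
        feat = encode_feature(context, rec.ref, rec.alt, rec.tx_strand)
        encoded.append((rec.sample_id, feat))
        kept_strand.append(feat.strand)
    if not encoded:
        reason, n = drops.most_common(1)[0]
        raise ValueError(f"all {len(records)} records dropped (dominant reason: {reason}, n={n})")
    if include_strand is None:
        include_strand = all(s is not None for s in kept_strand)
    if include_strand and any(s is None for s in kept_strand):
        raise ValueError("include_strand=True but some retained mutations lack strand")
    if not include_strand:
        encoded = [
            (sid, MutationFeature(f.sub_type, f.flank_m2, f.flank_m1, f.flank_p1, f.flank_p2, None))
            for sid, f in encoded
        ]

    samples: list[str] = []
    feat_cols: dict[MutationFeature, int] = {}
    cells: Counter[tuple[int, int]] = Counter()
    sample_rows: dict[str, int] = {}
    for sid, feat in encoded:
        if sid not in sample_rows:
            sample_rows[sid] = len(samples)
            samples.append(sid)
        if feat not in feat_cols:
            feat_cols[feat] = len(feat_cols)
        cells[(sample_rows[sid], feat_cols[feat])] += 1
    # canonical feature order for reproducible column layout
    order = sorted(feat_cols, key=lambda f: f.indices(include_strand))
    remap = {feat_cols[f]: j for j, f in enumerate(order)}
    counts = np.zeros((len(samples), len(order)), dtype=np.int64)
    for (i, j), c in cells.items():
        counts[i, remap[j]] = c
    if drops:
        logger.info("dropped records: %s", dict(drops))
    return MutationCatalog(
        samples=samples,
        features=order,
        counts=counts,
        includes_strand=include_strand,
        sample_meta={s: dict((sample_meta or {}).get(s, {})) for s in samples},
        drop_counts=dict(drops),
    )


def write_catalog(catalog: MutationCatalog, path: str | Path) -> None:
    """Write a catalog as a tab-delimited long table."""
    rows = []
    for i, sid in enumerate(catalog.samples):
        for j, feat in enumerate(catalog.features):
            c = catalog.counts[i, j]
            if c:
                rows.append(
                    (sid, feat.sub_type, feat.flank_m2, feat.flank_m1,
                     feat.flank_p1, feat.flank_p2, feat.strand or ".", int(c))
                )
    df = pd.DataFrame(
        rows,
        columns=["sample", "sub_type", "flank_m2", "flank_m1", "flank_p1",
                 "flank_p2", "strand", "count"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path, sample_meta: Mapping[str, Mapping] | None = None) -> MutationCatalog:
    """Read a catalog written by :func:`write_catalog`."""
    df = pd.read_csv(path, sep="\t", dtype={"count": np.int64})
    strands = df["strand"].astype(str)
    includes_strand = bool((strands != ".").all())
    samples: list[str] = []
    feat_cols: dict[MutationFeature, int] = {}
    triples = []
    for row in df.itertuples(index=False):
        sid = str(row.sample)
        if sid not in samples:
            samples.append(sid)
        feat = MutationFeature(
            row.sub_type, row.flank_m2, row.flank_m1, row.flank_p1, row.flank_p2,
            None if str(row.strand) == "." else str(row.strand),
        )
        if feat not in feat_cols:
            feat_cols[feat] = len(feat_cols)
        triples.append((samples.index(sid), feat_cols[feat], int(row.count)))
    order = sorted(feat_cols, key=lambda f: f.indices(includes_strand))
    remap = {feat_cols[f]: j for j, f in enumerate(order)}
    counts = np.zeros((len(samples), len(order)), dtype=np.int64)
    for i, j, c in triples:
        counts[i, remap[j]] += c
    return MutationCatalog(
        samples=samples, features=order, counts=counts,
        includes_strand=includes_strand,
        sample_meta={s: dict((sample_meta or {}).get(s, {})) for s in samples},
    )
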