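"""Cross-resolution signature comparison.

A factorized five-base signature can be expanded to the full product measure
over all feature combinations, or collapsed to the COSMIC 96-channel
trinucleotide resolution by marginalizing over the features the 96-channel
model does not measure (the -2/+2 flanks and strand).  Because the factors
are independent, the marginalization equals the product of the shared
factors (substitution type, 5' base, 3' base); both routes are implemented
and agree to floating-point precision.  Matching against a reference set
uses cosine similarity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog_io import BASES, POSITION_CATEGORIES, SUB_TYPES
from .signature_model import Signature, SignatureSet

#: canonical 96-channel labels, ordered by (sub_type, 5' base, 3' base)
CHANNELS_96: tuple[str, ...] = tuple(
    f"{b5}[{sub}]{b3}"
    for sub, b5, b3 in itertools.product(SUB_TYPES, BASES, BASES)
)


@dataclass
class Signature96:
    """Probability vector over the 96 trinucleotide substitution channels."""

    channels: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.shape != (96,):
            raise ValueError("Signature96 requires exactly 96 channels")
        if (self.channels < 0).any():
            raise ValueError("negative channel probabilities")
        if abs(self.channels.sum() - 1.0) > 1e-9:
            raise ValueError("channels must sum to 1")


def expand_full(signature: Signature) -> np.ndarray:
    """Expand factors to the product measure over all feature combinations.

    The returned vector is ordered lexicographically over positions
    (sub_type, -2, -1, +1, +2[, strand]); length 3072 with strand, 1536
    without, and sums to 1.
    """
    vec = np.array([1.0])
    for p in signature.positions:
        vec = np.outer(vec, signature.factors[p]).ravel()
    return vec


def collapse_to_96(signature: Signature, method: str = "product") -> Signature96:
    """Collapse a factorized signature to the 96-channel resolution.

    ``method="product"`` multiplies the three shared factors (substitution
    type, 5' base = -1 flank, 3' base = +1 flank).  ``method="marginalize"``
    expands the full product measure and sums over the -2/+2 flanks and
    strand.  The two routes are mathematically identical by independence.
    """
    if method == "product":
        channels = np.einsum(
            "s,f,t->sft",
            signature.factors["sub_type"],
            signature.factors["flank_m1"],
            signature.factors["flank_p1"],
        ).ravel()
    elif method == "marginalize":
        full = expand_full(signature)
        pos = signature.positions
        shape = tuple(len(POSITION_CATEGORIES[p]) for p in pos)
        cube = full.reshape(shape)
        # axes: 0=sub_type, 1=m2, 2=m1, 3=p1, 4=p2, (5=strand)
        axes = tuple(i for i, p in enumerate(pos) if p in ("flank_m2", "flank_p2", "strand"))
        channels = cube.sum(axis=axes).ravel()
    else:
        raise ValueError(f"unknown method {method!r}")
    channels = channels / channels.sum()
    return Signature96(channels, name=signature.name)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u| |v|); in [0, 1] for non-negative vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _as_96(entry, name: str) -> Signature96:
    if isinstance(entry, Signature96):
        return entry
    if isinstance(entry, Signature):
        return collapse_to_96(entry)
    raise TypeError(f"reference {name!r} is neither Signature nor Signature96")


def match_to_reference(
    queries: SignatureSet,
    reference: Mapping[str, "Signature96 | Signature"],
    resolution: str = "96",
) -> pd.DataFrame:
    """All pairwise cosine similarities between query and reference signatures.

    ``resolution="96"`` collapses everything to the 96 channels.
    ``resolution="full-shared"`` expands factorized signatures over the
    intersection of their feature structures (dropping strand when either
    side lacks it); it requires every reference entry to be factorized.
    Returns a table with one row per query x reference pair and a ``best``
    flag marking each query's best match.
    """
    if not reference:
        raise ValueError("reference set is empty")
    rows = []
    if resolution == "96":
        ref_vecs = {name: _as_96(entry, name).channels for name, entry in reference.items()}
        query_vecs = {
            (sig.name or f"sig_{k + 1}"): collapse_to_96(sig).channels
            for k, sig in enumerate(queries.signatures)
        }
    elif resolution == "full-shared":
        if not all(isinstance(e, Signature) for e in reference.values()):
            raise ValueError(
                "full-shared resolution requires factorized reference signatures; "
                "96-channel references have no common full projection"
            )
        shared_strand = queries.includes_strand and all(
            e.includes_strand for e in reference.values()
        )
        ref_vecs = {
            name: expand_full(e if shared_strand else e.drop_strand())
            for name, e in reference.items()
        }
        query_vecs = {
            (sig.name or f"sig_{k + 1}"): expand_full(
                sig if shared_strand else sig.drop_strand()
            )
            for k, sig in enumerate(queries.signatures)
        }
    else:
        raise ValueError(f"unknown resolution {resolution!r}")

    for qname, qvec in query_vecs.items():
        sims = {rname: cosine_similarity(qvec, rvec) for rname, rvec in ref_vecs.items()}
        best = max(sims, key=sims.get)
        for rname, sim in sims.items():
            rows.append((qname, rname, sim, rname == best))
    return pd.DataFrame(rows, columns=["query", "reference", "cosine", "best"])


# ---------------------------------------------------------------------------
# COSMIC-format 96-channel tables


def _normalize_channel_label(label: str) -> str:
    label = label.strip()
    if len(label) == 7 and label[1] == "[" and label[5] == "]":
        return label
    raise ValueError(f"unrecognized channel label {label!r}")


def read_cosmic(path: str | Path) -> dict[str, Signature96]:
    """Read a COSMIC-style SBS table (channel rows x signature columns).

    The first column holds channel labels like ``A[C>A]A``; rows may appear
    in any order and are normalized to the canonical ordering.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    label_col = df.columns[0]
    labels = [_normalize_channel_label(str(x)) for x in df[label_col]]
    if sorted(labels) != sorted(CHANNELS_96):
        raise ValueError("table does not contain exactly the 96 SBS channels")
    order = [labels.index(ch) for ch in CHANNELS_96]
    out = {}
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=np.float64)[order]
        out[str(col)] = Signature96(vals / vals.sum(), name=str(col))
    return out


def write_cosmic(signatures: Mapping[str, Signature96], path: str | Path) -> None:
    data = {"Type": list(CHANNELS_96)}
    for name, sig in signatures.items():
        data[name] = sig.channels
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.12g")
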