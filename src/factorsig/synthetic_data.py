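"""Synthetic mutation catalogs with known ground truth.

Generators for factorized signature sets, per-sample catalogs spanning
non-hypermutated (~hundreds of mutations) to hypermutated (~thousands)
regimes, paired trunk/branch groups with a controllable exposure shift and
VAF/purity structure, and small random reference genomes for I/O tests.
Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalog_io import (
    BASES,
    POSITION_CATEGORIES,
    SUB_TYPES,
    MutationCatalog,
    MutationFeature,
    MutationRecord,
    positions_for,
)
from .exposure_testing import PairedExposureData
from .signature_model import ExposureMatrix, Signature, SignatureSet, _prob_matrix, _theta_stack

#: (sub_type, 5' base) anchor pairs for well-separated presets, e.g. a
#: C>A signature with a 5' C, or a C>T signature with a 5' G — the
#: qualitative patterns seen in MMR-deficient colon tumors.
_ANCHOR_PAIRS = [(s, b) for s in SUB_TYPES for b in BASES]

#: mean mutation counts per regime; heavy-tailed burdens are drawn from a
#: negative binomial with this dispersion
COUNT_REGIMES = {"low": 200.0, "hypermutated": 5000.0}
NB_DISPERSION = 5.0


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run."""

    signature_set: SignatureSet
    exposures: ExposureMatrix | None
    sample_counts: np.ndarray | None
    seed: int
    mu_trunk: np.ndarray | None = None
    mu_branch: np.ndarray | None = None
    shift: np.ndarray | None = None
    purity: dict[str, float] | None = None


def make_signature_set(
    K: int,
    separation: str = "well_separated",
    includes_strand: bool = True,
    seed: int = 0,
) -> SignatureSet:
    """Draw K factorized signatures.

    ``well_separated`` anchors each signature on a distinct (substitution
    type, 5' base) pair with 0.85 of the factor mass, keeping the remaining
    positions near-uniform, so that expanded signatures have low pairwise
    cosine similarity.  ``random`` draws every factor from Dirichlet(0.5).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    pos = positions_for(includes_strand)
    sigs: list[Signature] = []
    if separation == "well_separated":
        if K > len(_ANCHOR_PAIRS):
            raise ValueError(f"well_separated mode supports at most {len(_ANCHOR_PAIRS)} signatures")
        pairs = [_ANCHOR_PAIRS[i] for i in rng.permutation(len(_ANCHOR_PAIRS))[:K]]
        for k, (sub, b5) in enumerate(pairs):
            factors = {}
            for p in pos:
                cats = POSITION_CATEGORIES[p]
                if p == "sub_type":
                    v = np.full(len(cats), 0.15 / (len(cats) - 1))
                    v[cats.index(sub)] = 0.85
                elif p == "flank_m1":
                    v = np.full(len(cats), 0.15 / (len(cats) - 1))
                    v[cats.index(b5)] = 0.85
                else:
                    v = rng.dirichlet(np.full(len(cats), 10.0))
                factors[p] = v / v.sum()
            sigs.append(Signature(factors, name=f"true_{k + 1}"))
    elif separation == "random":
        for k in range(K):
            factors = {
                p: rng.dirichlet(np.full(len(POSITION_CATEGORIES[p]), 0.5))
                for p in pos
            }
            sigs.append(Signature(factors, name=f"true_{k + 1}"))
    else:
        raise ValueError(f"unknown separation {separation!r}")
    return SignatureSet(sigs, includes_strand)


def _draw_counts(rng: np.random.Generator, n: int, regime: str) -> np.ndarray:
    if regime == "mixed":
        regimes = rng.choice(["low", "hypermutated"], size=n, p=[0.8, 0.2])
        return np.array([_draw_counts(rng, 1, r)[0] for r in regimes])
    mean = COUNT_REGIMES[regime]
    p = NB_DISPERSION / (NB_DISPERSION + mean)
    draws = rng.negative_binomial(NB_DISPERSION, p, size=n)
    return np.maximum(draws, 1)


def _full_measures(signature_set: SignatureSet) -> np.ndarray:
    """(K, n_combinations) expanded product measure per signature."""
    from .signature_compare import expand_full

    return np.stack([expand_full(s) for s in signature_set.signatures])


def _sample_feature_counts(
    rng: np.random.Generator,
    full: np.ndarray,
    exposure: np.ndarray,
    n: int,
) -> np.ndarray:
    """Draw n mutations: a component per mutation, then its feature.

    Equivalent to per-mutation categorical sampling, done as nested
    multinomials over the expanded feature space.
    """
    per_comp = rng.multinomial(n, exposure)
    total = np.zeros(full.shape[1], dtype=np.int64)
    for k, m in enumerate(per_comp):
        if m:
            total += rng.multinomial(m, full[k])
    return total


def _catalog_from_count_rows(
    samples: list[str],
    rows: np.ndarray,  # (n_samples, n_combinations) over the full feature space
    includes_strand: bool,
    sample_meta: dict | None = None,
) -> MutationCatalog:
    from .catalog_io import all_features

    observed = np.nonzero(rows.sum(axis=0) > 0)[0]
    space = all_features(includes_strand)
    return MutationCatalog(
        samples=list(samples),
        features=[space[j] for j in observed],
        counts=rows[:, observed],
        includes_strand=includes_strand,
        sample_meta=dict(sample_meta or {}),
    )


def simulate_catalog(
    signature_set: SignatureSet,
    n_samples: int,
    exposure_prior: float | np.ndarray | ExposureMatrix = 1.0,
    count_regime: str = "low",
    count_range: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[MutationCatalog, SimulationTruth]:
    """Simulate a mutation catalog from known signatures and exposures.

    Exposures are drawn per sample from a symmetric or explicit Dirichlet
    prior unless an explicit :class:`ExposureMatrix` is given; per-sample
    totals come from a heavy-tailed negative binomial in the chosen regime,
    or uniformly from ``count_range`` when given.
    """
    rng = np.random.default_rng(seed)
    K = signature_set.K
    if isinstance(exposure_prior, ExposureMatrix):
        if exposure_prior.values.shape != (n_samples, K):
            raise ValueError("explicit exposures have wrong shape")
        E = exposure_prior.values
    else:
        alpha = np.broadcast_to(np.asarray(exposure_prior, dtype=np.float64), (K,))
        E = rng.dirichlet(alpha, size=n_samples)
    if count_range is not None:
        totals = rng.integers(count_range[0], count_range[1] + 1, size=n_samples)
    else:
        totals = _draw_counts(rng, n_samples, count_regime)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    full = _full_measures(signature_set)
    rows = np.stack(
        [_sample_feature_counts(rng, full, E[i], int(totals[i])) for i in range(n_samples)]
    )
    catalog = _catalog_from_count_rows(samples, rows, signature_set.includes_strand)
    truth = SimulationTruth(
        signature_set=signature_set,
        exposures=ExposureMatrix(samples, E),
        sample_counts=totals,
        seed=seed,
    )
    return catalog, truth


def simulate_trunk_branch(
    signature_set: SignatureSet,
    n_samples: int,
    base_mu: Sequence[float] | None = None,
    shift: Sequence[float] | None = None,
    n_per_group: int = 500,
    purity_range: tuple[float, float] = (0.7, 1.0),
    group_concentration: float = 50.0,
    with_records: bool = True,
    seed: int = 0,
) -> tuple[PairedExposureData, list[MutationRecord], SimulationTruth]:
    """Simulate matched trunk/branch groups with a controllable exposure shift.

    The trunk group mean is ``base_mu + shift`` and the branch mean
    ``base_mu`` (``shift`` sums to zero; the default places +0.096 on the
    first signature, spread evenly over the rest).  Per sample-group
    exposures are Dirichlet around the group mean with the given
    concentration.  Trunk VAFs are uniform on [0.25, purity/2], branch VAFs
    uniform on [0.02, 0.25); positions are synthetic placeholders.

    Returns the paired count data, the flat VAF-annotated record list
    (sample ids carry no suffix; purity is in the truth object), and the
    ground truth.
    """
    rng = np.random.default_rng(seed)
    K = signature_set.K
    if base_mu is None:
        base_mu = np.full(K, 1.0 / K)
    base_mu = np.asarray(base_mu, dtype=np.float64)
    if shift is None:
        shift = np.full(K, -0.096 / (K - 1)) if K > 1 else np.zeros(K)
        if K > 1:
            shift[0] = 0.096
    shift = np.asarray(shift, dtype=np.float64)
    if abs(shift.sum()) > 1e-9:
        raise ValueError("shift must sum to 0")
    mu_trunk = base_mu + shift
    mu_branch = base_mu.copy()
    for name, mu in (("trunk", mu_trunk), ("branch", mu_branch)):
        if (mu < 0).any() or abs(mu.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} group mean is not a valid simplex point")

    samples = [f"P{i + 1:03d}" for i in range(n_samples)]
    purity = {
        s: float(rng.uniform(purity_range[0], purity_range[1])) for s in samples
    }
    includes_strand = signature_set.includes_strand
    full = _full_measures(signature_set)
    group_rows = {"trunk": [], "branch": []}
    records: list[MutationRecord] = []
    chrom_cycle = [str(c) for c in range(1, 23)]
    for s in samples:
        for g, mu in (("trunk", mu_trunk), ("branch", mu_branch)):
            q = rng.dirichlet(np.maximum(group_concentration * mu, 1e-6))
            group_rows[g].append(_sample_feature_counts(rng, full, q, n_per_group))
            if g == "trunk":
                vafs = rng.uniform(0.25, 0.5 * purity[s], size=n_per_group)
            else:
                vafs = rng.uniform(0.02, 0.25 - 1e-9, size=n_per_group)
            # VAFs are always drawn so counts are invariant to with_records
            if with_records:
                for j, vaf in enumerate(vafs):
                    records.append(
                        MutationRecord(
                            sample_id=s,
                            chrom=chrom_cycle[j % 22],
                            pos=1000 + j,
                            ref="C", alt="T", vaf=float(vaf),
                        )
                    )
    trunk_rows = np.stack(group_rows["trunk"])
    branch_rows = np.stack(group_rows["branch"])
    from .catalog_io import all_features

    observed = np.nonzero((trunk_rows.sum(axis=0) + branch_rows.sum(axis=0)) > 0)[0]
    space = all_features(includes_strand)
    data = PairedExposureData(
        sample_ids=samples,
        trunk_counts=trunk_rows[:, observed],
        branch_counts=branch_rows[:, observed],
        features=[space[j] for j in observed],
        signature_set=signature_set,
    )
    truth = SimulationTruth(
        signature_set=signature_set, exposures=None, sample_counts=None,
        seed=seed, mu_trunk=mu_trunk, mu_branch=mu_branch, shift=shift,
        purity=purity,
    )
    return data, records, truth


def make_toy_reference(
    n_chroms: int = 2, length: int = 100, seed: int = 0
) -> tuple[str, list[tuple[str, int, str]]]:
    """Random reference FASTA text plus plantable positions with known contexts.

    Returns the FASTA string (chromosomes named ``chr1`` ...) and a list of
    (chrom, 1-based position, true 5-base context) for every position with a
    full in-bounds window.
    """
    if length < 5:
        raise ValueError("length must be >= 5")
    rng = np.random.default_rng(seed)
    fasta_lines = []
    positions = []
    for c in range(1, n_chroms + 1):
        name = f"chr{c}"
        seq = "".join(rng.choice(list(BASES), size=length))
        fasta_lines.append(f">{name}")
        fasta_lines.append(seq)
        for pos in range(3, length - 1):  # 1-based, full window in bounds
            positions.append((name, pos, seq[pos - 3 : pos + 2]))
    return "\n".join(fasta_lines) + "\n", positions


def expected_feature_distribution(
    signature_set: SignatureSet, exposure: np.ndarray, features: list[MutationFeature]
) -> np.ndarray:
    """Mixture probability of each listed feature — convenience for tests."""
    feat_idx = np.array(
        [f.indices(signature_set.includes_strand) for f in features], dtype=np.int64
    )
    theta = _theta_stack(signature_set.signatures, signature_set.includes_strand)
    P = _prob_matrix(theta, feat_idx)
    return exposure @ P
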