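"""Factorized mixed-membership signature model and its EM fit.

A signature is a product of independent categorical distributions, one per
feature position (substitution type, each of four flanking bases, optional
transcription strand); the probability of a mutation feature under a
signature is the product of the per-position factor probabilities.  A sample
draws each mutation from a mixture of K signatures with sample-specific
mixing weights (exposures).  Fitting maximizes the multinomial mixture
likelihood by EM over the aggregated unique-feature count table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .catalog_io import (
    POSITION_CATEGORIES,
    MutationCatalog,
    MutationFeature,
    positions_for,
)

_NORM_TOL = 1e-9
_LOG_FLOOR = 1e-10  # floor inside logs during iteration only


@dataclass
class Signature:
    """Per-position categorical factors; each factor vector sums to 1."""

    factors: dict[str, np.ndarray]
    name: str | None = None

    def __post_init__(self) -> None:
        self.factors = {p: np.asarray(v, dtype=np.float64) for p, v in self.factors.items()}
        for p, v in self.factors.items():
            cats = POSITION_CATEGORIES.get(p)
            if cats is None:
                raise ValueError(f"unknown factor position {p!r}")
            if v.shape != (len(cats),):
                raise ValueError(f"factor {p!r} has wrong length {v.shape}")
            if (v < 0).any():
                raise ValueError(f"factor {p!r} has negative entries")
            if abs(v.sum() - 1.0) > _NORM_TOL:
                raise ValueError(f"factor {p!r} does not sum to 1 (sum={v.sum()!r})")

    @property
    def includes_strand(self) -> bool:
        return "strand" in self.factors

    @property
    def positions(self) -> tuple[str, ...]:
        return positions_for(self.includes_strand)

    def drop_strand(self) -> "Signature":
        if not self.includes_strand:
            return self
        return Signature(
            {p: v.copy() for p, v in self.factors.items() if p != "strand"},
            name=self.name,
        )


@dataclass
class SignatureSet:
    signatures: list[Signature]
    includes_strand: bool
    background: Signature | None = None

    def __post_init__(self) -> None:
        for s in self.signatures:
            if s.includes_strand != self.includes_strand:
                raise ValueError("signature strand structure mismatch")
        if self.background is not None and self.background.includes_strand != self.includes_strand:
            raise ValueError("background strand structure mismatch")

    @property
    def K(self) -> int:
        return len(self.signatures)

    @property
    def n_components(self) -> int:
        return self.K + (1 if self.background is not None else 0)

    @property
    def components(self) -> list[Signature]:
        out = list(self.signatures)
        if self.background is not None:
            out.append(self.background)
        return out


@dataclass
class ExposureMatrix:
    """Per-sample mixing weights over components; rows sum to 1."""

    samples: list[str]
    values: np.ndarray  # (n_samples, n_components)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.samples):
            raise ValueError("exposure shape mismatch")
        if (self.values < 0).any():
            raise ValueError("negative exposures")
        if np.abs(self.values.sum(axis=1) - 1.0).max() > _NORM_TOL:
            raise ValueError("exposure rows must sum to 1")


@dataclass
class FitResult:
    signature_set: SignatureSet
    exposures: ExposureMatrix
    loglik: float
    n_iterations: int
    converged: bool
    loglik_trace: list[float]
    seed: int
    n_restarts: int
    empty_samples: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Probabilities


def feature_probability(signature: Signature, feature: MutationFeature) -> float:
    """Product over positions of the factor probability of the feature's category."""
    if signature.includes_strand and feature.strand is None:
        raise ValueError("signature includes strand but feature lacks it")
    prob = 1.0
    for p in signature.positions:
        cats = POSITION_CATEGORIES[p]
        prob *= float(signature.factors[p][cats.index(feature.category(p))])
    return prob


def _theta_stack(signatures: list[Signature], includes_strand: bool) -> list[np.ndarray]:
    """Per-position (n_components, n_categories) factor matrices."""
    pos = positions_for(includes_strand)
    return [np.stack([s.factors[p] for s in signatures]) for p in pos]


def _prob_matrix(theta: list[np.ndarray], feat_idx: np.ndarray) -> np.ndarray:
    """(n_components, n_features) feature probabilities from stacked factors."""
    P = np.ones((theta[0].shape[0], feat_idx.shape[0]))
    for p, th in enumerate(theta):
        P *= th[:, feat_idx[:, p]]
    return P


def log_likelihood(
    catalog: MutationCatalog,
    signature_set: SignatureSet,
    exposures: ExposureMatrix,
) -> float:
    """Aggregated multinomial mixture log-likelihood.

    Returns ``-inf`` when some observed feature has zero probability under
    the mixture for its sample.
    """
    if signature_set.includes_strand != catalog.includes_strand:
        raise ValueError("catalog/signature strand structure mismatch")
    if exposures.values.shape != (catalog.n_samples, signature_set.n_components):
        raise ValueError("exposure dimensions do not match catalog/signatures")
    theta = _theta_stack(signature_set.components, signature_set.includes_strand)
    P = _prob_matrix(theta, catalog.feature_index_matrix())
    M = exposures.values @ P  # (n_samples, n_features)
    C = catalog.counts
    observed = C > 0
    if (M[observed] <= 0.0).any():
        return float("-inf")
    return float((C[observed] * np.log(M[observed])).sum())


# ---------------------------------------------------------------------------
# EM


def _init_params(
    rng: np.random.Generator,
    K: int,
    n_components: int,
    n_samples: int,
    includes_strand: bool,
) -> tuple[list[np.ndarray], np.ndarray]:
    pos = positions_for(includes_strand)
    theta = [rng.dirichlet(np.ones(len(POSITION_CATEGORIES[p])), size=K) for p in pos]
    E = rng.dirichlet(np.ones(n_components), size=n_samples)
    return theta, E


def _em_once(
    C: np.ndarray,
    feat_idx: np.ndarray,
    theta: list[np.ndarray],
    E: np.ndarray,
    bg_theta: list[np.ndarray] | None,
    max_iter: int,
    tol: float,
) -> tuple[list[np.ndarray], np.ndarray, list[float], bool]:
    """One EM run from the given starting point.

    ``theta`` holds the K free signatures; ``bg_theta`` the optional fixed
    background appended as an extra mixture component whose factors are not
    updated.
    """
    K = theta[0].shape[0]
    n_positions = len(theta)
    onehots = [
        np.eye(th.shape[1])[feat_idx[:, p]] for p, th in enumerate(theta)
    ]  # (n_features, n_cats) per position
    trace: list[float] = []
    converged = False
    row_tot = C.sum(axis=1, keepdims=True)
    empty = (row_tot[:, 0] == 0)
    for _ in range(max_iter):
        full_theta = (
            theta if bg_theta is None
            else [np.vstack([theta[p], bg_theta[p]]) for p in range(n_positions)]
        )
        P = _prob_matrix(full_theta, feat_idx)  # (n_components, n_features)
        M = E @ P
        ll = float((C * np.log(np.maximum(M, _LOG_FLOOR))).sum())
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
            break
        # E-step statistics: S[k,f] = P[k,f] * sum_d C[d,f] E[d,k] / M[d,f]
        ratio = C / np.maximum(M, _LOG_FLOOR)
        S = P * (E.T @ ratio)
        # M-step exposures: responsibility totals per sample
        E = E * (ratio @ P.T)
        E_sum = E.sum(axis=1, keepdims=True)
        E = np.where(E_sum > 0, E / np.maximum(E_sum, _LOG_FLOOR), 1.0 / E.shape[1])
        # M-step factors from responsibility-weighted marginal counts
        for p in range(n_positions):
            A = S[:K] @ onehots[p]  # (K, n_cats)
            A_sum = A.sum(axis=1, keepdims=True)
            theta[p] = np.where(A_sum > 0, A / np.maximum(A_sum, _LOG_FLOOR), 1.0 / A.shape[1])
    if empty.any():
        E[empty] = 1.0 / E.shape[1]
    return theta, E, trace, converged


def em_fit(
    catalog: MutationCatalog,
    K: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
    n_restarts: int = 10,
    seed: int = 0,
    background: Signature | None = None,
    init: tuple[SignatureSet, ExposureMatrix] | None = None,
) -> FitResult:
    """Fit K signatures and per-sample exposures by EM.

    Multiple random restarts (symmetric Dirichlet(1) initialization) guard
    against local maxima; the restart with the best final log-likelihood
    wins, ties broken by lowest restart index.  When ``init`` is given a
    single run starts from those estimates (used for warm-started bootstrap
    refits).  A ``background`` signature, if supplied, is appended as a
    fixed component whose exposure weight is estimated but whose factors are
    never updated.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if catalog.n_mutations == 0:
        raise ValueError("catalog is empty")
    if K > catalog.n_features:
        warnings.warn(
            f"K={K} exceeds the {catalog.n_features} distinct observed features",
            stacklevel=2,
        )
    includes_strand = catalog.includes_strand
    if background is not None and background.includes_strand != includes_strand:
        raise ValueError("background strand structure mismatch")
    feat_idx = catalog.feature_index_matrix()
    C = catalog.counts.astype(np.float64)
    n_components = K + (1 if background is not None else 0)
    bg_theta = (
        None if background is None
        else _theta_stack([background], includes_strand)
    )

    rng = np.random.default_rng(seed)
    best = None
    n_runs = 1 if init is not None else n_restarts
    for restart in range(n_runs):
        if init is not None:
            theta = [
                np.stack([s.factors[p] for s in init[0].signatures])
                for p in positions_for(includes_strand)
            ]
            E = init[1].values.copy()
        else:
            theta, E = _init_params(rng, K, n_components, catalog.n_samples, includes_strand)
        theta, E, trace, converged = _em_once(C, feat_idx, theta, E, bg_theta, max_iter, tol)
        if best is None or trace[-1] > best[3][-1]:
            best = (theta, E, converged, trace)

    theta, E, converged, trace = best
    pos = positions_for(includes_strand)
    signatures = [
        Signature({p: theta[i][k] for i, p in enumerate(pos)}, name=f"sig_{k + 1}")
        for k in range(K)
    ]
    sigset = SignatureSet(signatures, includes_strand, background=background)
    empties = [s for s, t in zip(catalog.samples, catalog.sample_totals) if t == 0]
    return FitResult(
        signature_set=sigset,
        exposures=ExposureMatrix(list(catalog.samples), E),
        loglik=trace[-1],
        n_iterations=len(trace),
        converged=converged,
        loglik_trace=trace,
        seed=seed,
        n_restarts=n_runs,
        empty_samples=empties,
    )


# ---------------------------------------------------------------------------
# Serialization (12 significant digits, round-trip stable)


def write_signature_set(sigset: SignatureSet, path) -> None:
    import pandas as pd

    rows = []
    for k, sig in enumerate(sigset.components):
        name = sig.name or (f"sig_{k + 1}" if k < sigset.K else "background")
        for p in sig.positions:
            for cat, prob in zip(POSITION_CATEGORIES[p], sig.factors[p]):
                rows.append((name, p, cat, float(f"{prob:.12g}")))
    pd.DataFrame(rows, columns=["signature", "position", "category", "probability"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_signature_set(path) -> SignatureSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    names = list(dict.fromkeys(df["signature"]))
    sigs: list[Signature] = []
    background = None
    includes_strand = "strand" in set(df["position"])
    for name in names:
        sub = df[df["signature"] == name]
        factors = {}
        for p in positions_for(includes_strand):
            block = sub[sub["position"] == p].set_index("category")["probability"]
            vec = np.array([block[c] for c in POSITION_CATEGORIES[p]])
            factors[p] = vec / vec.sum()
        sig = Signature(factors, name=str(name))
        if name == "background":
            background = sig
        else:
            sigs.append(sig)
    return SignatureSet(sigs, includes_strand, background=background)


def write_exposures(exposures: ExposureMatrix, path, names: list[str] | None = None) -> None:
    import pandas as pd

    n = exposures.values.shape[1]
    cols = names or [f"sig_{k + 1}" for k in range(n)]
    pd.DataFrame(exposures.values, index=exposures.samples, columns=cols).to_csv(
        path, sep="\t", index_label="sample", float_format="%.12g"
    )


def read_exposures(path) -> ExposureMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col="sample")
    values = df.to_numpy(dtype=np.float64)
    values = values / values.sum(axis=1, keepdims=True)
    return ExposureMatrix([str(s) for s in df.index], values)
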