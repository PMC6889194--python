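"""Choosing the number of signatures K by BIC and bootstrap standard errors.

BIC uses the total mutation count as the number of observations (mutations
are the sampling unit of the multinomial mixture).  Free parameters per
signature: 5 for the substitution type, 3 per flanking base (x4), and 1 for
strand when present; exposures add (n_components - 1) per sample.  Bootstrap
standard errors resample each sample's mutations with replacement, refit
from the point estimate, align replicate signatures to the point estimate by
greedy best-cosine matching, and take per-parameter standard deviations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog_io import MutationCatalog, positions_for
from .signature_model import FitResult, Signature, SignatureSet, em_fit
from .signature_compare import cosine_similarity, expand_full

logger = logging.getLogger(__name__)


def compute_bic(
    loglik: float,
    K: int,
    n_samples: int,
    includes_strand: bool,
    has_background: bool,
    n_mutations: int,
) -> float:
    """-2 loglik + P ln(N) with N the total mutation count.

    P = K * (5 + 4*3 + [1 if strand]) + n_samples * (K + [1 if background] - 1).
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    per_sig = 5 + 4 * 3 + (1 if includes_strand else 0)
    n_components = K + (1 if has_background else 0)
    n_params = K * per_sig + n_samples * (n_components - 1)
    return -2.0 * loglik + n_params * np.log(n_mutations)


def n_free_parameters(
    K: int, n_samples: int, includes_strand: bool, has_background: bool
) -> int:
    per_sig = 5 + 4 * 3 + (1 if includes_strand else 0)
    return K * per_sig + n_samples * (K + (1 if has_background else 0) - 1)


def greedy_align(reference: SignatureSet, replicate: SignatureSet) -> list[int]:
    """Permutation mapping reference index -> replicate index by best cosine.

    Greedy: the globally most similar unmatched pair is matched first; ties
    broken by lowest signature index.
    """
    ref_vecs = [expand_full(s) for s in reference.signatures]
    rep_vecs = [expand_full(s) for s in replicate.signatures]
    K = len(ref_vecs)
    sims = np.array([[cosine_similarity(r, q) for q in rep_vecs] for r in ref_vecs])
    perm = [-1] * K
    used_ref, used_rep = set(), set()
    flat = sorted(
        ((i, j) for i in range(K) for j in range(K)),
        key=lambda ij: (-sims[ij], ij[0], ij[1]),
    )
    for i, j in flat:
        if i not in used_ref and j not in used_rep:
            perm[i] = j
            used_ref.add(i)
            used_rep.add(j)
    return perm


@dataclass
class BootstrapSE:
    """Per-parameter bootstrap standard errors, shaped like the fit."""

    factor_se: list[dict[str, np.ndarray]]  # per signature, per position
    exposure_se: np.ndarray  # (n_samples, n_components)
    n_effective: int  # replicates that contributed
    n_dropped: int = 0

    @property
    def max_se(self) -> float:
        vals = [v.max() for sig in self.factor_se for v in sig.values()]
        vals.append(self.exposure_se.max())
        return float(max(vals))

    @property
    def mean_se(self) -> float:
        vals = np.concatenate(
            [v.ravel() for sig in self.factor_se for v in sig.values()]
            + [self.exposure_se.ravel()]
        )
        return float(vals.mean())


def bootstrap_se(
    catalog: MutationCatalog,
    fit: FitResult,
    B: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> BootstrapSE:
    """Bootstrap standard errors for all factor and exposure parameters.

    Each replicate resamples every sample's mutations with replacement
    (multinomial over its observed features at the same total), refits the
    model warm-started at the point estimate, aligns the replicate
    signatures to the point estimate, and contributes one draw per
    parameter.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    pos = positions_for(catalog.includes_strand)
    K = fit.signature_set.K
    factor_draws: list[dict[str, list[np.ndarray]]] = [
        {p: [] for p in pos} for _ in range(K)
    ]
    exposure_draws: list[np.ndarray] = []
    n_dropped = 0
    totals = catalog.sample_totals
    probs = catalog.counts / np.maximum(totals[:, None], 1)
    empty = totals == 0
    if empty.any():  # multinomial needs a valid pvals row even when n=0
        probs[empty] = 1.0 / catalog.n_features
    for _ in range(B):
        rep_counts = rng.multinomial(totals, probs)
        rep_catalog = MutationCatalog(
            samples=list(catalog.samples),
            features=list(catalog.features),
            counts=rep_counts,
            includes_strand=catalog.includes_strand,
            sample_meta=catalog.sample_meta,
        )
        try:
            rep_fit = em_fit(
                rep_catalog,
                K,
                max_iter=max_iter,
                tol=tol,
                seed=int(rng.integers(2**31)),
                background=fit.signature_set.background,
                init=(fit.signature_set, fit.exposures),
            )
        except Exception as exc:  # replicate fit failure
            logger.warning("bootstrap replicate dropped: %s", exc)
            n_dropped += 1
            continue
        perm = greedy_align(fit.signature_set, rep_fit.signature_set)
        for k in range(K):
            rep_sig = rep_fit.signature_set.signatures[perm[k]]
            for p in pos:
                factor_draws[k][p].append(rep_sig.factors[p])
        col_perm = list(perm) + (
            [K] if fit.signature_set.background is not None else []
        )
        exposure_draws.append(rep_fit.exposures.values[:, col_perm])
    n_eff = B - n_dropped
    if n_dropped > 0.2 * B:
        raise RuntimeError(f"{n_dropped}/{B} bootstrap replicates failed")
    factor_se = [
        {p: np.std(np.stack(factor_draws[k][p]), axis=0, ddof=1) for p in pos}
        for k in range(K)
    ]
    exposure_se = np.std(np.stack(exposure_draws), axis=0, ddof=1)
    return BootstrapSE(factor_se, exposure_se, n_effective=n_eff, n_dropped=n_dropped)


@dataclass
class SelectionResult:
    table: pd.DataFrame  # K, loglik, n_params, bic, max_bootstrap_se, mean_bootstrap_se
    chosen_k: int
    all_se_above_threshold: bool
    fits: dict[int, FitResult] = field(default_factory=dict)


def select_k(
    catalog: MutationCatalog,
    k_range,
    B: int = 20,
    se_threshold: float = 0.05,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 1000,
    tol: float = 1e-6,
    background: Signature | None = None,
) -> SelectionResult:
    """Scan K over ``k_range``; choose the BIC minimizer among stable fits.

    A fit is stable when its maximum bootstrap SE is at or below
    ``se_threshold``.  If no scanned K is stable, the overall BIC minimizer
    is returned with ``all_se_above_threshold=True``.
    """
    k_values = sorted(set(int(k) for k in k_range))
    if not k_values:
        raise ValueError("k_range is empty")
    rows = []
    fits: dict[int, FitResult] = {}
    rng = np.random.default_rng(seed)
    for K in k_values:
        fit_seed = int(rng.integers(2**31))
        boot_seed = int(rng.integers(2**31))
        fit = em_fit(
            catalog, K, max_iter=max_iter, tol=tol, n_restarts=n_restarts,
            seed=fit_seed, background=background,
        )
        fits[K] = fit
        se = bootstrap_se(catalog, fit, B=B, seed=boot_seed)
        bic = compute_bic(
            fit.loglik, K, catalog.n_samples, catalog.includes_strand,
            background is not None, catalog.n_mutations,
        )
        rows.append(
            dict(
                K=K, loglik=fit.loglik,
                n_params=n_free_parameters(
                    K, catalog.n_samples, catalog.includes_strand, background is not None
                ),
                bic=bic, max_bootstrap_se=se.max_se, mean_bootstrap_se=se.mean_se,
            )
        )
    table = pd.DataFrame(rows)
    stable = table[table["max_bootstrap_se"] <= se_threshold]
    if len(stable):
        chosen = int(stable.loc[stable["bic"].idxmin(), "K"])
        flag = False
    else:
        chosen = int(table.loc[table["bic"].idxmin(), "K"])
        flag = True
        warnings.warn(
            "no scanned K met the bootstrap-SE threshold; returning overall BIC minimum",
            stacklevel=2,
        )
    return SelectionResult(table=table, chosen_k=chosen, all_se_above_threshold=flag, fits=fits)
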