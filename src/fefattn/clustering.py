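"""Cell-type clustering: feature screening, Gaussian mixtures, dip tests.

Candidate per-cell features (P2T, CV, CV2, Lv, FR, FF, AUROC) are z-scored
and screened down to a subset whose span explains at least 90% of the total
variance.  Diagonal-covariance Gaussian mixtures are fitted over k = 2..12
with multiple seeded restarts; AIC and BIC select the cluster count, with a
narrow/broad width-mixing tiebreak when they disagree.  Within-cluster
waveform-width bimodality is assessed with the calibrated Hartigan dip test,
FDR-adjusted across clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .attention import bh_fdr
from .dip import dip_statistic, dip_test_calibrated
from .metrics import NARROW_P2T_US

CANDIDATE_FEATURES = ("p2t_us", "cv", "cv2", "lv", "fr", "ff", "auroc")
K_RANGE = range(2, 13)


@dataclass
class ClusterModel:
    selected_features: list[str]
    explained_fraction: float
    sweep: pd.DataFrame
    k_aic: int
    k_bic: int
    k_used: int
    assignments: np.ndarray
    cell_ids: list[str]
    composition: pd.DataFrame | None = None
    dip_results: pd.DataFrame | None = None
    excluded_cells: list[str] = field(default_factory=list)


def zscore(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    return (m - m.mean(axis=0)) / m.std(axis=0, ddof=0)


def _span_explained(z: np.ndarray, cols: list[int]) -> float:
    """Fraction of total variance of z captured by the span of z[:, cols]."""
    sub = z[:, cols]
    coef, *_ = np.linalg.lstsq(sub, z, rcond=None)
    resid = z - sub @ coef
    total = np.sum(z**2)
    return 1.0 - np.sum(resid**2) / total


def screen_parameters(
    features: pd.DataFrame,
    threshold: float = 0.90,
) -> tuple[list[str], float]:
    """Greedy forward feature selection to >= ``threshold`` of total variance.

    Features are ranked by their total squared PCA loading weighted by each
    component's explained-variance ratio; selection then proceeds greedily,
    at each step adding the feature whose inclusion most increases the
    fraction of total variance explained by the selected columns' span
    (rank order breaks ties), until the threshold is reached.  A feature
    nearly collinear with the current selection adds no span and is
    therefore passed over — only one of a duplicated pair is kept.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    names = list(features.columns)
    if len(names) < 2:
        raise ValueError("need >= 2 candidate features")
    z = zscore(features.to_numpy())
    if z.shape[0] < len(names) + 1:
        raise ValueError("need more cells than features")
    # PCA via SVD of the z-scored matrix
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    evr = s**2 / np.sum(s**2)
    importance = (vt**2 * evr[:, None]).sum(axis=0)
    rank = {i: r for r, i in enumerate(np.argsort(importance)[::-1])}
    selected: list[int] = []
    remaining = list(range(len(names)))
    frac = 0.0
    while remaining and frac < threshold:
        gains = {
            idx: _span_explained(z, selected + [idx]) for idx in remaining
        }
        best = max(remaining, key=lambda i: (gains[i], -rank[i]))
        selected.append(best)
        remaining.remove(best)
        frac = gains[best]
    return [names[i] for i in selected], float(frac)


def _mixture_params(k: int, d: int) -> int:
    """Free parameters of a diagonal-covariance k-component mixture."""
    return k * 2 * d + (k - 1)


#: variance floor for mixture components, in squared z-score units.
#: Cluster features are estimates with sampling error of roughly 0.1 z
#: units; a fitted component narrower than that noise floor is a
#: maximum-likelihood artefact, not a cell class.
REG_COVAR = 0.01


def fit_mixture_sweep(
    z: np.ndarray,
    k_range=K_RANGE,
    restarts: int = 100,
    seed: int = 0,
    reg_covar: float = REG_COVAR,
) -> tuple[pd.DataFrame, dict[int, GaussianMixture]]:
    """Best-of-restarts diagonal GMM per k, with AIC/BIC.

    Each restart is an independently seeded single-init fit; restarts whose
    hard assignment leaves a component with fewer than 2 members are
    discarded.  Component variances are floored at ``reg_covar`` (see
    :data:`REG_COVAR`).  Deterministic given ``seed``.
    """
    n, d = z.shape
    if n < max(k_range) * 3:
        raise ValueError("too few cells for the requested k range")
    ss = np.random.SeedSequence(seed)
    rows = []
    best_models: dict[int, GaussianMixture] = {}
    for k in k_range:
        best_ll = -np.inf
        best = None
        best_seed = -1
        for child in ss.spawn(restarts):
            rs = int(child.generate_state(1)[0] % (2**31))
            gm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                n_init=1,
                random_state=rs,
                reg_covar=reg_covar,
            )
            try:
                gm.fit(z)
            except ValueError:
                continue
            labels = gm.predict(z)
            if np.min(np.bincount(labels, minlength=k)) < 2:
                continue  # degenerate component
            ll = gm.score(z) * n
            if ll > best_ll:
                best_ll, best, best_seed = ll, gm, rs
        if best is None:
            continue
        p = _mixture_params(k, d)
        rows.append(
            dict(
                k=k,
                loglik=best_ll,
                n_params=p,
                aic=2 * p - 2 * best_ll,
                bic=p * np.log(n) - 2 * best_ll,
                seed=best_seed,
            )
        )
        best_models[k] = best
    return pd.DataFrame(rows), best_models


def width_mixing_score(assignments: np.ndarray, p2t_us: np.ndarray) -> float:
    """Summed per-cluster minority fraction of narrow/broad width classes."""
    narrow = np.asarray(p2t_us) <= NARROW_P2T_US
    score = 0.0
    for c in np.unique(assignments):
        mask = assignments == c
        frac_narrow = narrow[mask].mean()
        score += min(frac_narrow, 1.0 - frac_narrow)
    return float(score)


def select_k(
    sweep: pd.DataFrame,
    models: dict[int, GaussianMixture],
    z: np.ndarray,
    p2t_us: np.ndarray,
    criterion: str = "AIC",
) -> tuple[int, np.ndarray]:
    """Cluster count by AIC/BIC argmin, width-mixing tiebreak on disagreement.

    When AIC and BIC select different k, the solution whose clusters mix
    narrow and broad spiking cells less (lower summed minority fraction)
    is preferred.
    """
    if sweep.empty:
        raise ValueError("empty sweep")
    k_aic = int(sweep.loc[sweep["aic"].idxmin(), "k"])
    k_bic = int(sweep.loc[sweep["bic"].idxmin(), "k"])
    if k_aic == k_bic:
        k = k_aic
    else:
        scores = {}
        for k_cand in (k_aic, k_bic):
            labels = models[k_cand].predict(z)
            scores[k_cand] = width_mixing_score(labels, p2t_us)
        k = min((k_aic, k_bic), key=lambda kk: (scores[kk], kk != k_aic))
    edge = sweep["k"].min(), sweep["k"].max()
    if k in edge and sweep.shape[0] > 2:
        crit = "aic" if criterion.upper() == "AIC" else "bic"
        vals = sweep.sort_values("k")[crit].to_numpy()
        if np.all(np.diff(vals) > 0) or np.all(np.diff(vals) < 0):
            import warnings

            warnings.warn(f"monotone {criterion} sweep; boundary k={k}")
    return k, models[k].predict(z)


def dip_by_cluster(
    assignments: np.ndarray,
    p2t_us: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibrated dip test of the P2T distribution within each cluster,
    FDR-adjusted across clusters; clusters under 10 cells are untestable."""
    ss = np.random.SeedSequence(seed)
    rows = []
    clusters = np.unique(assignments)
    for c, child in zip(clusters, ss.spawn(len(clusters))):
        vals = np.asarray(p2t_us)[assignments == c]
        if vals.size < 10:
            rows.append(dict(cluster=int(c), n=int(vals.size),
                             dip=float("nan"), p=float("nan"), testable=False))
            continue
        d, p = dip_test_calibrated(vals, n_boot=n_boot,
                                   seed=np.random.default_rng(child))
        rows.append(dict(cluster=int(c), n=int(vals.size), dip=d, p=p,
                         testable=True))
    df = pd.DataFrame(rows)
    testable = df["testable"].to_numpy()
    adj = np.full(len(df), np.nan)
    if testable.any():
        adj[testable] = bh_fdr(df.loc[testable, "p"].to_numpy())
    df["p_fdr"] = adj
    return df


def summarize_clusters(
    assignments: np.ndarray,
    features: pd.DataFrame,
    p2t_us: np.ndarray,
) -> pd.DataFrame:
    """Per-cluster composition: narrow/broad counts, feature means +/- SD,
    and width-based labels (B* broad-dominated, N* otherwise)."""
    narrow = np.asarray(p2t_us) <= NARROW_P2T_US
    rows = []
    for c in np.unique(assignments):
        mask = assignments == c
        row = dict(
            cluster=int(c),
            n=int(mask.sum()),
            n_narrow=int(narrow[mask].sum()),
            n_broad=int((~narrow[mask]).sum()),
        )
        row["minority_fraction"] = min(row["n_narrow"], row["n_broad"]) / row["n"]
        for col in features.columns:
            vals = features.loc[mask, col]
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if mask.sum() > 1 else 0.0
        rows.append(row)
    df = pd.DataFrame(rows)
    # label broad-dominated clusters B1.., others N1.., in cluster order
    labels = []
    b = n = 0
    for _, row in df.iterrows():
        if row["n_broad"] >= row["n_narrow"]:
            b += 1
            labels.append(f"B{b}")
        else:
            n += 1
            labels.append(f"N{n}")
    df["label"] = labels
    return df


def cluster_cells(
    features: pd.DataFrame,
    cell_ids: list[str],
    threshold: float = 0.90,
    k_range=K_RANGE,
    restarts: int = 100,
    seed: int = 0,
    n_boot: int = 10_000,
) -> ClusterModel:
    """Full clustering stage: screen, sweep, select, dip, summarise.

    Cells with any missing feature are excluded and listed on the model.
    """
    complete = features.notna().all(axis=1).to_numpy()
    excluded = [cid for cid, ok in zip(cell_ids, complete) if not ok]
    feats = features.loc[complete].reset_index(drop=True)
    ids = [cid for cid, ok in zip(cell_ids, complete) if ok]
    selected, frac = screen_parameters(feats, threshold)
    z = zscore(feats[selected].to_numpy())
    p2t = feats["p2t_us"].to_numpy()
    sweep, models = fit_mixture_sweep(z, k_range, restarts, seed)
    k_aic = int(sweep.loc[sweep["aic"].idxmin(), "k"])
    k_bic = int(sweep.loc[sweep["bic"].idxmin(), "k"])
    k, labels = select_k(sweep, models, z, p2t)
    comp = summarize_clusters(labels, feats[selected], p2t)
    dips = dip_by_cluster(labels, p2t, n_boot=n_boot, seed=seed + 1)
    return ClusterModel(
        selected_features=selected,
        explained_fraction=frac,
        sweep=sweep,
        k_aic=k_aic,
        k_bic=k_bic,
        k_used=k,
        assignments=labels,
        cell_ids=ids,
        composition=comp,
        dip_results=dips,
        excluded_cells=excluded,
    )
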