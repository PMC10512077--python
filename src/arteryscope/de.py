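"""Per-layer case-versus-control differential expression.

The response is log2(Q3-normalized count + pseudocount). Within each layer
the model is

    log2 expression ~ status + (1 | patient)

fit by REML, with a Wald z test on the status coefficient (an optional
between-within t approximation is available). When every patient contributes
exactly one ROI to the layer the random intercept is unidentifiable and the
fit drops to ordinary least squares — the equivalent model — implemented as
a vectorized pooled-variance two-group comparison with exact t p-values.

A gene is called a DEG when its signed fold change exceeds the threshold
(|FC| > 2 by default) and its Benjamini-Hochberg adjusted p falls below
alpha (0.01 by default); adjustment is performed within each layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

CASE_STATUS = "GCA"
CONTROL_STATUS = "control"

MODEL_LMM = "lmm"
MODEL_OLS = "ols_fallback"
MODEL_UNTESTABLE = "untestable"

DEG_UP = "up"
DEG_DOWN = "down"
DEG_NS = "ns"


@dataclass(frozen=True)
class ModelSpec:
    """Thresholds and numerical choices of the DE model."""

    alpha: float = 0.01
    fc_threshold: float = 2.0
    pseudocount: float = 1.0
    adjust_scope: str = "layer"  # or "global"
    inference: str = "wald_z"  # or "t" (between-within df approximation)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.adjust_scope not in ("layer", "global"):
            raise ValueError("adjust_scope must be 'layer' or 'global'")
        if self.inference not in ("wald_z", "t"):
            raise ValueError("inference must be 'wald_z' or 't'")


def log2_expression(normalized: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    return np.log2(normalized + pseudocount)


def signed_fold_change(beta: np.ndarray) -> np.ndarray:
    """2^beta for beta >= 0, -2^(-beta) for beta < 0 (so |FC| >= 1 always)."""
    beta = np.asarray(beta, dtype=float)
    return np.where(beta >= 0, 2.0**beta, -(2.0 ** (-beta)))


def _ols_two_group(y: np.ndarray, is_case: np.ndarray) -> Tuple[np.ndarray, ...]:
    """Vectorized OLS of y ~ status over genes (rows). Exact t p-values.

    Equivalent to per-gene OLS with an intercept and a case indicator:
    beta = mean(case) - mean(control), pooled residual variance, df = n - 2.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1 = int(is_case.sum())
    n0 = int((~is_case).sum())
    yc, y0 = y[:, is_case], y[:, ~is_case]
    beta = yc.mean(axis=1) - y0.mean(axis=1)
    ss = ((yc - yc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y0 - y0.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n0 - 2
    s2 = ss / df
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def _fit_mixedlm(
    y: np.ndarray, is_case: np.ndarray, groups: np.ndarray, inference: str
) -> Tuple[float, float, float, str]:
    exog = np.column_stack([np.ones_like(y), is_case.astype(float)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, exog, groups=groups)
            fit = model.fit(reml=True)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        if not np.isfinite(beta) or not np.isfinite(se) or se <= 0:
            raise ValueError("non-finite mixed-model estimate")
    except Exception:
        beta, se, p = (float(v[0]) for v in _ols_two_group(y, is_case))
        return beta, se, p, MODEL_OLS
    stat = beta / se
    if inference == "t":
        # between-within approximation: df = #groups - 2
        df = max(len(np.unique(groups)) - 2, 1)
        p = float(2.0 * stats.t.sf(abs(stat), df))
    else:
        p = float(2.0 * stats.norm.sf(abs(stat)))
    return beta, se, p, MODEL_LMM


def fit_gene(
    y: pd.Series,
    meta: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    force_lmm: bool = False,
) -> Tuple[float, float, float, str]:
    """Fit one gene within one layer; returns (beta, se, p_raw, model_used).

    ``y`` is log2 expression indexed by ROI; ``meta`` is the ROI metadata
    restricted to the same layer (columns patient, status). With one ROI per
    patient the fit uses the equivalent OLS model unless ``force_lmm``.
    """
    meta = meta.loc[y.index]
    is_case = (meta["status"] == CASE_STATUS).to_numpy()
    yv = y.to_numpy(dtype=float)
    if is_case.sum() == 0 or (~is_case).sum() == 0 or np.ptp(yv) == 0.0:
        return 0.0, float("nan"), 1.0, MODEL_UNTESTABLE
    one_roi_per_patient = meta.groupby("patient").size().max() == 1
    if one_roi_per_patient and not force_lmm:
        beta, se, p = (float(v[0]) for v in _ols_two_group(yv, is_case))
        return beta, se, p, MODEL_OLS
    return _fit_mixedlm(yv, is_case, meta["patient"].to_numpy(), spec.inference)


def fit_layer(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    layer: str,
    spec: ModelSpec = ModelSpec(),
) -> pd.DataFrame:
    """DE fits for every gene in one layer.

    ``expr`` is the log2-transformed normalized matrix (genes x all ROIs).
    Returns a DataFrame indexed by gene: beta, se, p_raw, model_used.
    """
    layer_meta = meta[meta["layer"] == layer]
    rois = [r for r in expr.columns if r in layer_meta.index]
    if not rois:
        raise ValueError(f"no ROIs for layer {layer!r}")
    layer_meta = layer_meta.loc[rois]
    sub = expr[rois]
    is_case = (layer_meta["status"] == CASE_STATUS).to_numpy()

    n_case, n_ctrl = int(is_case.sum()), int((~is_case).sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError(
            f"layer {layer!r} needs >=2 ROIs per status group "
            f"(got {n_case} case / {n_ctrl} control)")

    y = sub.to_numpy(dtype=float)
    testable = np.ptp(y, axis=1) > 0.0
    beta = np.zeros(len(sub))
    se = np.full(len(sub), np.nan)
    p = np.ones(len(sub))
    model = np.full(len(sub), MODEL_UNTESTABLE, dtype=object)

    one_roi_per_patient = layer_meta.groupby("patient").size().max() == 1
    idx = np.flatnonzero(testable)
    if len(idx):
        if one_roi_per_patient:
            b, s, pv = _ols_two_group(y[idx], is_case)
            beta[idx], se[idx], p[idx] = b, s, pv
            model[idx] = MODEL_OLS
        else:
            groups = layer_meta["patient"].to_numpy()
            for i in idx:
                beta[i], se[i], p[i], model[i] = _fit_mixedlm(
                    y[i], is_case, groups, spec.inference)
    return pd.DataFrame(
        {"beta": beta, "se": se, "p_raw": p, "model_used": model}, index=sub.index
    )


def bh_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_raw), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_degs(fits: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> pd.DataFrame:
    """Attach p_adj, signed_fc and the DEG call to a layer's fit table."""
    out = fits.copy()
    out["p_adj"] = bh_adjust(out["p_raw"])
    out["signed_fc"] = signed_fold_change(out["beta"].to_numpy())
    up = (out["signed_fc"] > spec.fc_threshold) & (out["p_adj"] < spec.alpha)
    down = (out["signed_fc"] < -spec.fc_threshold) & (out["p_adj"] < spec.alpha)
    out["deg"] = np.select([up, down], [DEG_UP, DEG_DOWN], default=DEG_NS)
    out.loc[out["model_used"] == MODEL_UNTESTABLE, "deg"] = DEG_NS
    return out


def run_de(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    layers: Optional[Sequence[str]] = None,
) -> Dict[str, pd.DataFrame]:
    """Fit and classify every layer; returns {layer: DeResult table}.

    With ``adjust_scope='layer'`` BH runs within each layer (each layer is
    its own family); with ``'global'`` one adjustment spans all layers.
    """
    expr = log2_expression(normalized, spec.pseudocount)
    if layers is None:
        layers = list(dict.fromkeys(meta["layer"]))
    fits = {layer: fit_layer(expr, meta, layer, spec) for layer in layers}
    if spec.adjust_scope == "layer":
        return {layer: classify_degs(f, spec) for layer, f in fits.items()}
    pooled = np.concatenate([f["p_raw"].to_numpy() for f in fits.values()])
    adj = bh_adjust(pooled)
    results = {}
    offset = 0
    for layer, f in fits.items():
        out = f.copy()
        out["p_adj"] = adj[offset: offset + len(f)]
        offset += len(f)
        out["signed_fc"] = signed_fold_change(out["beta"].to_numpy())
        up = (out["signed_fc"] > spec.fc_threshold) & (out["p_adj"] < spec.alpha)
        down = (out["signed_fc"] < -spec.fc_threshold) & (out["p_adj"] < spec.alpha)
        out["deg"] = np.select([up, down], [DEG_UP, DEG_DOWN], default=DEG_NS)
        out.loc[out["model_used"] == MODEL_UNTESTABLE, "deg"] = DEG_NS
        results[layer] = out
    return results


def top_degs(result: pd.DataFrame, n: int = 20, direction: str = DEG_UP) -> List[str]:
    """Top-n DEGs of one direction, ranked by |beta| (ties: p_adj, gene id)."""
    sub = result[result["deg"] == direction].copy()
    sub["_abs_beta"] = sub["beta"].abs()
    sub = sub.sort_values(
        ["_abs_beta", "p_adj"], ascending=[False, True], kind="mergesort"
    )
    # stable mergesort + pre-sorted index makes gene id the final tie-break
    sub = sub.loc[sub.index.sort_values()].sort_values(
        ["_abs_beta", "p_adj"], ascending=[False, True], kind="mergesort"
    )
    return list(sub.index[:n])
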