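"""Quantitative evaluation: NRMSE, global SSIM, MAE, and the ablation table.

Metric definitions (per evaluated volume, inside the evaluation mask):

  MAE    = (1/N) Σ_i |ŷ_i − y_i|                                  [HU]
  NRMSE  = sqrt((1/N) Σ_i (ŷ_i − y_i)²) / (y_max − y_min)         [unitless]
  SSIM   = (2 μ_ŷ μ_y + c1)(2 σ_ŷy + c2) /
           ((μ_ŷ² + μ_y² + c1)(σ_ŷ² + σ_y² + c2))                 [global window]

with c1 = (k1 L)², c2 = (k2 L)², k1 = 0.01, k2 = 0.03 and L the dynamic
range (default 4271, the −1200..3071 HU clip window).  NRMSE normalises by
the reference range by default; normalising by the prediction range is
available as an option.  Smaller NRMSE/MAE and larger SSIM indicate better
quality.  Volume-level metrics are aggregated as mean ± sd over the test
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .net import PLANES, predict_multiplanar, predict_volume
from .train import TrainConfig, ablation_config, fit
from .volume import HU_RANGE, Volume

SSIM_K1 = 0.01
SSIM_K2 = 0.03


def _masked(pred: Volume, ref: Volume, mask):
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {ref.shape}")
    a = pred.data.astype(np.float64)
    b = ref.data.astype(np.float64)
    if mask is not None:
        m = mask.data if hasattr(mask, "data") else np.asarray(mask, dtype=bool)
        if m.shape != a.shape:
            raise ValueError("mask grid mismatch")
        a, b = a[m], b[m]
    else:
        a, b = a.ravel(), b.ravel()
    return a, b


def mae(pred: Volume, ref: Volume, mask=None) -> float:
    """Mean absolute voxel difference (HU) within the evaluation mask."""
    a, b = _masked(pred, ref, mask)
    return float(np.mean(np.abs(a - b)))


def nrmse(pred: Volume, ref: Volume, mask=None,
          normalizer: str = "reference") -> float:
    """RMS voxel error divided by the intensity range of the normalising
    volume ('reference' by default, 'prediction' optionally)."""
    a, b = _masked(pred, ref, mask)
    norm = b if normalizer == "reference" else a
    rng = float(norm.max() - norm.min())
    if rng == 0:
        raise ValueError("zero dynamic range in the normalising volume")
    return float(np.sqrt(np.mean((a - b) ** 2)) / rng)


def ssim_global(pred: Volume, ref: Volume, mask=None, k1: float = SSIM_K1,
                k2: float = SSIM_K2, L: float = HU_RANGE) -> float:
    """Single-window SSIM: global means, variances and covariance."""
    a, b = _masked(pred, ref, mask)
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    return float(((2 * mu_a * mu_b + c1) * (2 * cov + c2)) /
                 ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))


@dataclass
class MetricsReport:
    """Per-volume and aggregate NRMSE/SSIM/MAE for one model."""

    model_id: str
    per_volume: pd.DataFrame          # columns: volume, nrmse, ssim, mae

    @property
    def n(self) -> int:
        return len(self.per_volume)

    def aggregate(self) -> pd.DataFrame:
        agg = self.per_volume[["nrmse", "ssim", "mae"]].agg(["mean", "std"])
        agg.loc["std"] = agg.loc["std"].fillna(0.0)
        return agg

    def summary(self) -> str:
        agg = self.aggregate()
        parts = [f"{m}={agg.loc['mean', m]:.4f}±{agg.loc['std', m]:.4f}"
                 for m in ("nrmse", "ssim", "mae")]
        return f"{self.model_id} (n={self.n}): " + ", ".join(parts)


def evaluate(pred_volumes, ref_volumes, model_id: str = "model",
             masks=None, normalizer: str = "reference") -> MetricsReport:
    """Per-volume metrics within the overlap mask, aggregated mean ± sd."""
    if len(pred_volumes) != len(ref_volumes):
        raise ValueError("pred/ref lists must have equal length")
    if masks is None:
        masks = [None] * len(pred_volumes)
    rows = []
    for i, (p, r, m) in enumerate(zip(pred_volumes, ref_volumes, masks)):
        rows.append({"volume": i,
                     "nrmse": nrmse(p, r, m, normalizer=normalizer),
                     "ssim": ssim_global(p, r, m),
                     "mae": mae(p, r, m)})
    return MetricsReport(model_id, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ablation


def _paired_p(base: np.ndarray, other: np.ndarray) -> float:
    """Paired t-test p-value; identical samples give p = 1."""
    diff = base - other
    if np.allclose(diff, 0.0, atol=1e-12):
        return 1.0
    if np.std(diff, ddof=1) == 0:
        return 0.0
    return float(stats.ttest_rel(base, other).pvalue)


def holm_correct(pvals: list[float], alpha: float = 0.05):
    """Holm step-down adjusted p-values and rejection flags."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj, adj < alpha


def predict_with_config(vol: Volume, models: dict, planes) -> Volume:
    if len(planes) == 1:
        return predict_volume(vol, models[planes[0]], planes[0])
    return predict_multiplanar(vol, {p: models[p] for p in planes})


def run_ablation(train_pairs, test_pairs, configs: dict[str, TrainConfig],
                 model_spec, masks=None, alpha: float = 0.05,
                 verbose: bool = False):
    """Train each configuration, evaluate on the test pairs, and compare to
    the uncorrected degraded input with Holm-corrected paired t-tests.

    ``train_pairs``/``test_pairs`` are (cbct, mdct) tuples, already
    prepared (registered, intensity-matched, clipped).  Returns
    (table: DataFrame, reports: {model_id: MetricsReport},
    histories: {model_id: per-epoch loss DataFrame}).
    """
    if len(test_pairs) < 2:
        raise ValueError("paired testing needs at least 2 test pairs")
    refs = [m for _, m in test_pairs]
    inputs = [c for c, _ in test_pairs]
    reports = {"baseline": evaluate(inputs, refs, "baseline", masks)}
    histories = {}
    for name, cfg in configs.items():
        models, histories[name] = fit(train_pairs, model_spec, cfg,
                                      verbose=verbose)
        preds = [predict_with_config(v, models, cfg.planes) for v in inputs]
        reports[name] = evaluate(preds, refs, name, masks)

    base = reports["baseline"].per_volume
    rows = []
    raw_p = {}
    for name, rep in reports.items():
        agg = rep.aggregate()
        row = {"model": name}
        for metric in ("nrmse", "ssim", "mae"):
            row[f"{metric}_mean"] = agg.loc["mean", metric]
            row[f"{metric}_sd"] = agg.loc["std", metric]
        if name != "baseline":
            raw_p[name] = {m: _paired_p(base[m].to_numpy(),
                                        rep.per_volume[m].to_numpy())
                           for m in ("nrmse", "ssim", "mae")}
        rows.append(row)
    table = pd.DataFrame(rows)
    for metric in ("nrmse", "ssim", "mae"):
        names = list(raw_p)
        if names:
            adj, rej = holm_correct([raw_p[n][metric] for n in names], alpha)
            pcol = {n: a for n, a in zip(names, adj)}
            scol = {n: bool(r) for n, r in zip(names, rej)}
            table[f"{metric}_p_holm"] = table["model"].map(pcol)
            table[f"{metric}_significant"] = table["model"].map(scol)
    return table, reports, histories
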