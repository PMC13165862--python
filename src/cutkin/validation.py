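"""Agreement battery: R², RMSE, Spearman, Bland–Altman, and CMC with bands.

Pooled metrics (R², RMSE, Spearman, Bland–Altman bias and 95 % limits of
agreement) are computed over all concatenated test rows of a target;
waveform similarity (CMC, coefficient of multiple correlation) is computed
per trial over the 101-point stance axis and summarized by its median,
classified on the standard five-band scale: excellent (>= 0.95), very good
(>= 0.85), good (>= 0.75), moderate (>= 0.65), poor (< 0.65).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .modeling import Dataset, TrainedModel, feature_importances, predict_waveforms
from .preprocess import TARGET_NAMES

#: band lower bounds, scanned in order; boundary values go to the higher band
CMC_BANDS: tuple[tuple[str, float], ...] = (
    ("excellent", 0.95),
    ("very good", 0.85),
    ("good", 0.75),
    ("moderate", 0.65),
)

TARGET_UNITS: dict[str, str] = {
    name: ("BW" if name == "vgrf" else "Nm/kg") for name in TARGET_NAMES
}


def r_squared(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (can be negative)."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.size < 2:
        raise ValueError("need two equal-length series with n >= 2")
    ss_tot = np.sum((actual - actual.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined: actual series is constant")
    return float(1.0 - np.sum((actual - predicted) ** 2) / ss_tot)


def rmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.size < 1:
        raise ValueError("need two equal-length non-empty series")
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def spearman(actual: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with a two-sided p-value."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.size < 3:
        raise ValueError("need two equal-length series with n >= 3")
    if np.ptp(actual) == 0 or np.ptp(predicted) == 0:
        raise ValueError("Spearman correlation undefined for a constant input")
    res = _stats.spearmanr(actual, predicted)
    return float(res.statistic), float(res.pvalue)


def bland_altman(
    actual: np.ndarray, predicted: np.ndarray
) -> tuple[float, float, float]:
    """Bias and 95 % limits of agreement of d = predicted - actual.

    LoA = bias ± 1.96 × SD(d), SD with the unbiased (n−1) denominator.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.size < 2:
        raise ValueError("need two equal-length series with n >= 2")
    d = predicted - actual
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def cmc(actual_waveform: np.ndarray, predicted_waveform: np.ndarray) -> float:
    """Two-waveform coefficient of multiple correlation over the stance phase.

    With F = 2 waveforms over T time points, per-time means Ȳ_t and grand
    mean Ȳ::

        CMC = sqrt(1 - [Σ_t Σ_f (Y_ft − Ȳ_t)² / (T (F−1))]
                     / [Σ_t Σ_f (Y_ft − Ȳ)²  / (F T − 1)])

    When the within-time dispersion exceeds the overall dispersion the
    radicand is negative; the CMC is then complex by convention and returned
    as NaN (classified "poor").
    """
    a = np.asarray(actual_waveform, dtype=float)
    p = np.asarray(predicted_waveform, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("waveforms must be equal-length 1-D arrays")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(p))):
        raise ValueError("waveforms must be finite")
    Y = np.stack([a, p])  # (F=2, T)
    F, T = Y.shape
    ybar_t = Y.mean(axis=0)
    ybar = Y.mean()
    num = np.sum((Y - ybar_t) ** 2) / (T * (F - 1))
    den = np.sum((Y - ybar) ** 2) / (F * T - 1)
    if den == 0:
        raise ValueError("CMC undefined: both waveforms constant and identical")
    ratio = num / den
    if ratio > 1:
        return float("nan")
    return float(math.sqrt(1.0 - ratio))


def classify_cmc(value: float) -> str:
    """Map a CMC value (or NaN) to its agreement band."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "poor"
    if value > 1 + 1e-12:
        raise ValueError(f"CMC cannot exceed 1 (got {value})")
    for band, lo in CMC_BANDS:
        if value >= lo:
            return band
    return "poor"


def moving_average(x: np.ndarray, width: int = 5) -> np.ndarray:
    """Centered moving average for visual presentation only (edges shrink
    the window symmetrically); metrics are never computed on smoothed data."""
    x = np.asarray(x, dtype=float)
    half = width // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


@dataclass
class TargetAgreement:
    """All agreement statistics for one kinetic target."""

    target: str
    units: str
    r_squared: float
    rmse: float
    spearman_r: float
    spearman_p: float
    bias: float
    loa_low: float
    loa_high: float
    cmc_values: dict[str, float]  # per test trial (NaN allowed)
    cmc_median: float
    cmc_band: str
    top_features: list[tuple[str, float]]  # top-3 (name, percent)

    def to_dict(self) -> dict:
        d = {
            "target": self.target,
            "units": self.units,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "spearman_r": self.spearman_r,
            "spearman_p": self.spearman_p,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "cmc_values": {
                k: (None if math.isnan(v) else v) for k, v in self.cmc_values.items()
            },
            "cmc_median": None if math.isnan(self.cmc_median) else self.cmc_median,
            "cmc_band": self.cmc_band,
            "top_features": [[n, p] for n, p in self.top_features],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TargetAgreement":
        return cls(
            target=d["target"],
            units=d["units"],
            r_squared=d["r_squared"],
            rmse=d["rmse"],
            spearman_r=d["spearman_r"],
            spearman_p=d["spearman_p"],
            bias=d["bias"],
            loa_low=d["loa_low"],
            loa_high=d["loa_high"],
            cmc_values={
                k: (float("nan") if v is None else v)
                for k, v in d["cmc_values"].items()
            },
            cmc_median=float("nan") if d["cmc_median"] is None else d["cmc_median"],
            cmc_band=d["cmc_band"],
            top_features=[(n, p) for n, p in d["top_features"]],
        )


@dataclass
class AgreementReport:
    """Per-target agreement statistics plus optional mean-waveform plot data."""

    per_target: dict[str, TargetAgreement]
    plot_data: dict[str, dict] = field(default_factory=dict)

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            {
                "per_target": {k: v.to_dict() for k, v in self.per_target.items()},
                "plot_data": self.plot_data,
            },
            indent=indent,
        )

    @classmethod
    def from_json(cls, text: str) -> "AgreementReport":
        d = json.loads(text)
        return cls(
            per_target={
                k: TargetAgreement.from_dict(v) for k, v in d["per_target"].items()
            },
            plot_data=d.get("plot_data", {}),
        )

    def performance_table(self) -> pd.DataFrame:
        """R²/RMSE/Spearman table over all targets."""
        rows = [
            {
                "target": t.target,
                "units": t.units,
                "r_squared": round(t.r_squared, 3),
                "rmse": round(t.rmse, 3),
                "spearman_r": round(t.spearman_r, 3),
                "spearman_p": t.spearman_p,
            }
            for t in self.per_target.values()
        ]
        return pd.DataFrame(rows)

    def agreement_table(self) -> pd.DataFrame:
        """Bland–Altman bias and 95 % LoA per target."""
        rows = [
            {
                "target": t.target,
                "bias": round(t.bias, 3),
                "loa_low": round(t.loa_low, 3),
                "loa_high": round(t.loa_high, 3),
                "cmc_median": None if math.isnan(t.cmc_median) else round(t.cmc_median, 2),
                "cmc_band": t.cmc_band,
            }
            for t in self.per_target.values()
        ]
        return pd.DataFrame(rows)

    def importance_table(self) -> pd.DataFrame:
        rows = []
        for t in self.per_target.values():
            for name, pct in t.top_features:
                rows.append(
                    {"target": t.target, "feature": name, "contribution_pct": round(pct, 2)}
                )
        return pd.DataFrame(rows)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(self.to_json())
        self.performance_table().to_csv(
            directory / "performance.tsv", sep="\t", index=False
        )
        self.agreement_table().to_csv(
            directory / "agreement.tsv", sep="\t", index=False
        )
        self.importance_table().to_csv(
            directory / "importances.tsv", sep="\t", index=False
        )
        for target, pd_data in self.plot_data.items():
            pd.DataFrame(pd_data).to_csv(
                directory / f"waveform_{target}.tsv", sep="\t", index=False
            )


def build_report(
    models: dict[str, TrainedModel],
    test: Dataset,
    smooth_plot: bool = True,
) -> AgreementReport:
    """Assemble the full agreement report for all seven targets on a test set.

    Pooled metrics use all concatenated test rows; CMC is computed per trial.
    Mean-waveform plot data may be smoothed with a 5-point moving average for
    presentation — metrics are always computed on unsmoothed values.
    """
    missing = [t for t in TARGET_NAMES if t not in models]
    if missing:
        raise ValueError(f"missing trained models for targets: {missing}")
    per_target: dict[str, TargetAgreement] = {}
    plot_data: dict[str, dict] = {}
    for target in TARGET_NAMES:
        model = models[target]
        preds = predict_waveforms(model, test)
        actual_stack = np.stack([kt.waveform(target) for _, kt in test.trials])
        pred_stack = np.stack([preds[fm.key] for fm, _ in test.trials])
        pooled_a, pooled_p = actual_stack.ravel(), pred_stack.ravel()
        r, p = spearman(pooled_a, pooled_p)
        bias, lo, hi = bland_altman(pooled_a, pooled_p)
        cmc_vals = {
            fm.key: cmc(kt.waveform(target), preds[fm.key])
            for fm, kt in test.trials
        }
        cmc_arr = np.array(list(cmc_vals.values()))
        # NaN CMCs (complex-valued convention) count as worst when ranking
        med = float(np.median(np.nan_to_num(cmc_arr, nan=-1.0)))
        cmc_median = float("nan") if med == -1.0 else med
        per_target[target] = TargetAgreement(
            target=target,
            units=TARGET_UNITS[target],
            r_squared=r_squared(pooled_a, pooled_p),
            rmse=rmse(pooled_a, pooled_p),
            spearman_r=r,
            spearman_p=p,
            bias=bias,
            loa_low=lo,
            loa_high=hi,
            cmc_values=cmc_vals,
            cmc_median=cmc_median,
            cmc_band=classify_cmc(cmc_median),
            top_features=feature_importances(model)[:3],
        )
        mean_a, sd_a = actual_stack.mean(axis=0), actual_stack.std(axis=0)
        mean_p, sd_p = pred_stack.mean(axis=0), pred_stack.std(axis=0)
        if smooth_plot:
            mean_a, sd_a, mean_p, sd_p = (
                moving_average(v) for v in (mean_a, sd_a, mean_p, sd_p)
            )
        plot_data[target] = {
            "stance_pct": list(range(len(mean_a))),
            "actual_mean": mean_a.round(6).tolist(),
            "actual_sd": sd_a.round(6).tolist(),
            "predicted_mean": mean_p.round(6).tolist(),
            "predicted_sd": sd_p.round(6).tolist(),
        }
    return AgreementReport(per_target=per_target, plot_data=plot_data)
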