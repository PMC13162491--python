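"""Colony competition assays: competitive index and log2-fitness statistics.

A mixed colony yields one measurement pair (a_value, b_value) — fluorescent
colony areas in mm² or flow-cytometry cell proportions — for the two
competing strains.  The colony competitive index is

    CIC = (A_mutant / A_reference) / CIC_pa

where CIC_pa is the mean reference-pair ratio from control colonies, which
removes reporter-specific bias.  Because strain proportions are
compositional, downstream inference is carried out on log2-transformed
ratios: a two-sided one-sample t-test of mean log2 against zero (neutral
competitiveness), with an exact Wilcoxon signed-rank test as a small-sample
non-parametric robustness check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PROPORTION_TOLERANCE = 1e-6


@dataclass(frozen=True)
class CompetitionMeasurement:
    """One mixed colony: paired abundance measurements for two strains."""

    colony_id: str
    strain_a: str
    strain_b: str
    a_value: float
    b_value: float
    modality: str = "area"
    is_control: bool = False

    def __post_init__(self):
        if self.a_value < 0 or self.b_value < 0:
            raise ValueError(f"colony {self.colony_id}: negative measurement")
        if self.modality not in ("area", "proportion"):
            raise ValueError(f"colony {self.colony_id}: unknown modality {self.modality!r}")
        if self.modality == "proportion":
            if self.a_value + self.b_value > 1 + PROPORTION_TOLERANCE:
                raise ValueError(
                    f"colony {self.colony_id}: proportions sum to "
                    f"{self.a_value + self.b_value:.4f} > 1"
                )


def read_measurements(path) -> list[CompetitionMeasurement]:
    """Read the measurement CSV (colony_id, strain_a, strain_b, a_value, b_value,
    modality, is_control)."""
    df = pd.read_csv(path)
    required = {"colony_id", "strain_a", "strain_b", "a_value", "b_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(CompetitionMeasurement(
            colony_id=str(row.colony_id),
            strain_a=str(row.strain_a),
            strain_b=str(row.strain_b),
            a_value=float(row.a_value),
            b_value=float(row.b_value),
            modality=str(getattr(row, "modality", "area") or "area"),
            is_control=bool(getattr(row, "is_control", False)),
        ))
    return out


def write_measurements(measurements, path) -> None:
    pd.DataFrame(
        [
            {
                "colony_id": m.colony_id, "strain_a": m.strain_a,
                "strain_b": m.strain_b, "a_value": m.a_value, "b_value": m.b_value,
                "modality": m.modality, "is_control": m.is_control,
            }
            for m in measurements
        ]
    ).to_csv(path, index=False)


def control_ratio(controls) -> float:
    """Arithmetic mean of per-colony a/b ratios over control colonies (CIC_pa)."""
    controls = list(controls)
    if not controls:
        raise ValueError("control_ratio needs at least one control colony")
    ratios = []
    for m in controls:
        if m.b_value == 0:
            raise ValueError(f"control colony {m.colony_id}: b_value is zero")
        ratios.append(m.a_value / m.b_value)
    return float(np.mean(ratios))


def compute_cic(m: CompetitionMeasurement, cic_pa: float) -> float:
    """Colony competitive index (a/b)/CIC_pa; a zero a_value yields CIC = 0,
    which downstream log-scale tests must exclude explicitly."""
    if m.b_value == 0:
        raise ValueError(f"colony {m.colony_id}: b_value is zero")
    if cic_pa <= 0:
        raise ValueError(f"control ratio must be positive, got {cic_pa}")
    return (m.a_value / m.b_value) / cic_pa


WILCOXON_EXACT_MAX_N = 25


def _wilcoxon_p(log2_values: np.ndarray) -> float | None:
    """Two-sided one-sample Wilcoxon signed-rank p against zero.

    Exact null enumeration for n <= 25 (no ties/zeros); normal approximation
    with continuity correction otherwise.  Zero differences are dropped
    (Wilcoxon convention); returns None when nothing remains.
    """
    nonzero = log2_values[log2_values != 0]
    if nonzero.size == 0:
        return None
    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    method = "exact" if (nonzero.size <= WILCOXON_EXACT_MAX_N and not has_ties) else "approx"
    res = stats.wilcoxon(
        nonzero, alternative="two-sided", zero_method="wilcox",
        correction=(method == "approx"), method=method,
    )
    return float(res.pvalue)


@dataclass
class CompetitionResult:
    """Log2-scale fitness statistics for one comparison."""

    values: list = field(default_factory=list)       # CIC or raw ratios (original scale)
    log2_values: list = field(default_factory=list)
    n: int = 0
    mean_log2: float = float("nan")
    sd_log2: float = float("nan")
    t_stat: float | None = None
    df: int = 0
    p_two_sided: float | None = None
    wilcoxon_p: float | None = None
    fold_change: float = float("nan")
    control_ratio_used: float | None = None
    degenerate: bool = False
    n_excluded_nonpositive: int = 0
    original_scale_summary: dict | None = None

    def to_json(self, path=None):
        payload = {
            "n": self.n,
            "values": list(self.values),
            "log2_values": list(self.log2_values),
            "mean_log2": self.mean_log2,
            "sd_log2": self.sd_log2,
            "t_stat": self.t_stat,
            "df": self.df,
            "p_two_sided": self.p_two_sided,
            "wilcoxon_p": self.wilcoxon_p,
            "fold_change": self.fold_change,
            "control_ratio_used": self.control_ratio_used,
            "degenerate": self.degenerate,
            "n_excluded_nonpositive": self.n_excluded_nonpositive,
            "original_scale_summary": self.original_scale_summary,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload

    def to_text(self) -> str:
        lines = [
            f"n colonies              : {self.n}",
            f"mean log2 ratio         : {self.mean_log2:.3f}",
            f"sd log2 ratio           : {self.sd_log2:.3f}",
            f"fold change (2^mean)    : {self.fold_change:.3f}",
        ]
        if self.degenerate:
            lines.append("one-sample t            : degenerate (zero variance), p omitted")
        elif self.t_stat is not None:
            lines.append(
                f"one-sample t vs 0       : t = {self.t_stat:.2f}, df = {self.df}, "
                f"p = {self.p_two_sided:.3g}"
            )
        if self.wilcoxon_p is not None:
            lines.append(f"Wilcoxon signed-rank p  : {self.wilcoxon_p:.3g}")
        if self.control_ratio_used is not None:
            lines.append(f"control ratio (CIC_pa)  : {self.control_ratio_used:.4f}")
        if self.n_excluded_nonpositive:
            lines.append(
                f"excluded (CIC = 0)      : {self.n_excluded_nonpositive} colonies"
            )
        if self.original_scale_summary:
            s = self.original_scale_summary
            lines.append(
                "original scale          : "
                f"a = {s['mean_a']:.3f} ± {s['sd_a']:.3f}, "
                f"b = {s['mean_b']:.3f} ± {s['sd_b']:.3f} (mean ± SD)"
            )
        return "\n".join(lines)


def log2_fitness_test(values, values_are_log2: bool = False) -> CompetitionResult:
    """One-sample location analysis of log2 fitness ratios against zero.

    ``values`` are positive ratios (CIC or a/b) unless ``values_are_log2``.
    Returns mean/sd of log2 values, t = mean/(sd/sqrt(n)) with df = n-1 and
    the two-sided p from the t distribution, the Wilcoxon signed-rank p, and
    the fold change 2^mean.
    """
    values = list(values)
    if not values:
        raise ValueError("log2_fitness_test needs at least one value")
    if values_are_log2:
        log2_values = np.asarray(values, dtype=float)
        orig = list(np.exp2(log2_values))
    else:
        arr = np.asarray(values, dtype=float)
        if np.any(arr <= 0):
            raise ValueError(
                "non-positive ratio passed to log2_fitness_test; exclude zero-CIC "
                "colonies explicitly before testing"
            )
        log2_values = np.log2(arr)
        orig = list(arr)

    n = log2_values.size
    mean = float(np.mean(log2_values))
    result = CompetitionResult(
        values=orig,
        log2_values=[float(v) for v in log2_values],
        n=n,
        mean_log2=mean,
        fold_change=float(2.0 ** mean),
        df=n - 1,
    )
    if n >= 2:
        sd = float(np.std(log2_values, ddof=1))
        result.sd_log2 = sd
        if sd == 0.0:
            result.degenerate = True
        else:
            t = mean / (sd / math.sqrt(n))
            result.t_stat = float(t)
            result.p_two_sided = float(2.0 * stats.t.sf(abs(t), n - 1))
        result.wilcoxon_p = _wilcoxon_p(log2_values)
    else:
        result.sd_log2 = float("nan")
    return result


def pairwise_log_ratio(mixes) -> CompetitionResult:
    """Per-colony log2(a/b) analysis for direct pairwise competitions.

    Mirrors the compositional-data convention: statistics are computed on the
    unconstrained log-ratio scale, while the original-scale mean ± SD of both
    strains is reported alongside for interpretability.
    """
    mixes = list(mixes)
    if not mixes:
        raise ValueError("pairwise_log_ratio needs at least one colony")
    for m in mixes:
        if m.a_value <= 0 or m.b_value <= 0:
            raise ValueError(
                f"colony {m.colony_id}: non-positive measurement in pairwise ratio"
            )
    ratios = [m.a_value / m.b_value for m in mixes]
    result = log2_fitness_test(ratios)
    a_values = np.array([m.a_value for m in mixes], dtype=float)
    b_values = np.array([m.b_value for m in mixes], dtype=float)
    result.original_scale_summary = {
        "strain_a": mixes[0].strain_a,
        "strain_b": mixes[0].strain_b,
        "modality": mixes[0].modality,
        "mean_a": float(np.mean(a_values)),
        "sd_a": float(np.std(a_values, ddof=1)) if len(mixes) > 1 else 0.0,
        "mean_b": float(np.mean(b_values)),
        "sd_b": float(np.std(b_values, ddof=1)) if len(mixes) > 1 else 0.0,
    }
    return result


class CompetitionModel:
    """Competitive-index analysis of one strain-vs-reference comparison.

    Parameters
    ----------
    measurements
        Mixed-colony measurements for the mutant-vs-reference pairs
        (non-control rows).
    controls
        Control colonies (reference-vs-reference) used to compute the
        normalisation ratio CIC_pa.  When omitted, CIC_pa defaults to 1
        (already-normalised inputs).
    """

    def __init__(self, measurements, controls=None):
        self.measurements = [m for m in measurements if not m.is_control]
        self.controls = list(controls) if controls is not None else [
            m for m in measurements if m.is_control
        ]
        if not self.measurements:
            raise ValueError("no non-control measurements supplied")

    def fit(self) -> "CompetitionResults":
        cic_pa = control_ratio(self.controls) if self.controls else 1.0
        cic_values = [compute_cic(m, cic_pa) for m in self.measurements]
        positive = [v for v in cic_values if v > 0]
        n_excluded = len(cic_values) - len(positive)
        if not positive:
            raise ValueError("all CIC values are zero; nothing to test on the log scale")
        result = log2_fitness_test(positive)
        result.control_ratio_used = cic_pa
        result.n_excluded_nonpositive = n_excluded
        return CompetitionResults(self, cic_values, result)


class CompetitionResults:
    """Fitted competition analysis: per-colony CIC plus log2-scale inference."""

    def __init__(self, model: CompetitionModel, cic_values, result: CompetitionResult):
        self.model = model
        self.cic_values = cic_values
        self.result = result

    def __getattr__(self, name):
        try:
            return getattr(self.result, name)
        except AttributeError:
            raise AttributeError(name) from None

    def summary(self) -> str:
        pairs = {(m.strain_a, m.strain_b) for m in self.model.measurements}
        header = ", ".join(f"{a} vs {b}" for a, b in sorted(pairs))
        lines = [
            "Colony competitive index (CIC) analysis",
            "=" * 48,
            f"comparison              : {header}",
            "per-colony CIC          : "
            + ", ".join(f"{v:.3f}" for v in self.cic_values),
            self.result.to_text(),
        ]
        return "\n".join(lines)

    def to_json(self, path=None):
        payload = self.result.to_json()
        payload["cic_values"] = [float(v) for v in self.cic_values]
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
        return payload
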