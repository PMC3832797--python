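"""Input/output gain curves: assembly, sigmoid fits, kindled-vs-control contrasts.

The input/output relation of each region is the normalized response
magnitude as a function of stimulation frequency.  It is fitted with a
Hill-type sigmoid on linear frequency,

    R(f) = base + (top - base) / (1 + (f_half / f) ** hill),

whose midpoint parameter ``f_half`` is the half-maximal stimulation
frequency: R(f_half) = (base + top) / 2 exactly.  Inhibitory (layer III)
curves are fitted on the absolute normalized magnitude so that "activation
of inhibition" increases with frequency.

Group statistics are limited to means, SEMs and per-slice differences;
hypothesis testing is left to general-purpose statistics packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError
from .quantify import ResponseMeasure

MIN_FIT_FREQUENCIES = 4


def sigmoid(f, base, top, f_half, hill):
    """Hill-type dose/response curve on linear frequency."""
    f = np.asarray(f, dtype=float)
    return base + (top - base) / (1.0 + (f_half / f) ** hill)


def log_sigmoid(f, base, top, f_half, hill):
    """Logistic in log-frequency; same midpoint convention as :func:`sigmoid`."""
    f = np.asarray(f, dtype=float)
    return base + (top - base) / (1.0 + np.exp(-hill * (np.log(f) - np.log(f_half))))


_MODELS = {"hill": sigmoid, "log": log_sigmoid}


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted input/output curve parameters."""

    base: float
    top: float
    f_half: float
    hill: float
    rss: float
    converged: bool
    n_points: int = 0
    model: str = "hill"

    def predict(self, f):
        return _MODELS[self.model](f, self.base, self.top, self.f_half, self.hill)


@dataclass
class IoCurve:
    """Normalized response vs stimulation frequency for one region.

    ``points`` are ``(frequency_hz, normalized_magnitude, slice_id)`` tuples;
    per-frequency means and SEMs are available via :meth:`summary`.
    """

    region: str
    points: list[tuple[float, float, str]]
    fit: SigmoidFit | None = None

    def frequencies(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    def values(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def summary(self) -> pd.DataFrame:
        """Per-frequency mean and SEM (SEM is NaN for single-slice groups)."""
        rows = []
        by_freq: dict[float, list[float]] = {}
        for f, v, _ in self.points:
            by_freq.setdefault(float(f), []).append(v)
        for f in sorted(by_freq):
            vals = np.asarray(by_freq[f])
            sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            rows.append(
                {"frequency_hz": f, "mean": float(vals.mean()), "sem": sem, "n": len(vals)}
            )
        return pd.DataFrame(rows)


def assemble_io_curve(
    measures: Iterable[ResponseMeasure], region: str
) -> IoCurve:
    """Collect one region's normalized measures into an :class:`IoCurve`."""
    points = []
    for m in measures:
        if m.region != region:
            raise ValidationError(
                f"measure for region {m.region!r} mixed into {region!r} curve"
            )
        if m.normalized_magnitude is None:
            raise ValidationError(
                "measures must be normalized before curve assembly"
            )
        points.append((float(m.frequency_hz), float(m.normalized_magnitude), m.slice_id))
    points.sort(key=lambda p: (p[0], p[2]))
    return IoCurve(region=region, points=points)


def fit_sigmoid(
    curve: IoCurve,
    absolute: bool | str = "auto",
    min_dynamic_range: float = 0.2,
    model: str = "hill",
) -> SigmoidFit:
    """Least-squares sigmoid fit of an input/output curve.

    Parameters
    ----------
    absolute:
        Fit on ``|value|``.  The default ``"auto"`` rectifies when the median
        point is negative (inhibitory curves).
    min_dynamic_range:
        Fits are refused (``converged=False``) when the spread of the data is
        below this value — a flat curve has no meaningful midpoint.
    model:
        ``"hill"`` (linear frequency, default) or ``"log"`` (logistic in
        log-frequency).

    Initialization is deterministic: base = min, top = max, f_half = the
    frequency whose mean value is nearest the half-range crossing, hill = 2.
    """
    if model not in _MODELS:
        raise ValidationError(f"unknown sigmoid model {model!r}")
    freqs = curve.frequencies()
    vals = curve.values()
    if len(np.unique(freqs)) < MIN_FIT_FREQUENCIES:
        raise ValidationError(
            f"sigmoid fit needs >= {MIN_FIT_FREQUENCIES} distinct frequencies"
        )
    if not (np.isfinite(freqs).all() and np.isfinite(vals).all()):
        raise ValidationError("sigmoid fit requires finite points")
    if (freqs <= 0).any():
        raise ValidationError("frequencies must be positive")
    if absolute == "auto":
        absolute = bool(np.median(vals) < 0)
    if absolute:
        vals = np.abs(vals)

    failed = SigmoidFit(
        base=float("nan"), top=float("nan"), f_half=float("nan"),
        hill=float("nan"), rss=float("nan"), converged=False,
        n_points=len(vals), model=model,
    )
    if vals.max() - vals.min() < min_dynamic_range:
        return failed

    base0, top0 = float(vals.min()), float(vals.max())
    half = 0.5 * (base0 + top0)
    # frequency whose mean value is nearest the half-range crossing
    uniq = np.unique(freqs)
    means = np.array([vals[freqs == f].mean() for f in uniq])
    fhalf0 = float(uniq[np.argmin(np.abs(means - half))])
    p0 = [base0, top0, fhalf0, 2.0]
    bounds = ([-np.inf, -np.inf, 1e-3, 0.05], [np.inf, np.inf, 1e4, 50.0])
    try:
        popt, _ = curve_fit(
            _MODELS[model], freqs, vals, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError):
        return failed
    base, top, f_half, hill = (float(p) for p in popt)
    rss = float(np.sum((_MODELS[model](freqs, *popt) - vals) ** 2))
    converged = bool(top >= base and np.isfinite(rss))
    return SigmoidFit(
        base=base, top=top, f_half=f_half, hill=hill,
        rss=rss, converged=converged, n_points=len(vals), model=model,
    )


def half_max_frequency(fit: SigmoidFit) -> float:
    """The fitted half-maximal stimulation frequency, in Hz."""
    if not fit.converged:
        raise FitError("cannot report f_half of a non-converged fit")
    return fit.f_half


@dataclass
class FoldChangeContrast:
    """Control-vs-kindled differences from the 20 Hz-normalized response.

    ``per_slice`` holds one row per (group, slice, frequency) with the
    difference ``normalized value - normalized value at 20 Hz``;
    ``group_means`` aggregates them and ``gap`` is kindled minus control.
    """

    region: str
    per_slice: pd.DataFrame
    group_means: pd.DataFrame
    gap: dict[float, float] = field(default_factory=dict)


def fold_change_contrast(
    control: IoCurve,
    kindled: IoCurve,
    frequencies: Sequence[float] = (40.0, 60.0, 80.0),
    ref_freq: float = 20.0,
) -> FoldChangeContrast:
    """Per-slice difference of the normalized response from its 20 Hz value.

    By construction the difference at the reference frequency is 0.  Both
    curves must contain the reference frequency for every slice.
    """
    if control.region != kindled.region:
        raise ValidationError("contrast requires curves for the same region")

    def slice_values(curve: IoCurve, group: str) -> list[dict]:
        per_slice: dict[str, dict[float, float]] = {}
        for f, v, sid in curve.points:
            per_slice.setdefault(sid, {})[float(f)] = v
        rows = []
        for sid, values in per_slice.items():
            ref = next(
                (v for f, v in values.items() if np.isclose(f, ref_freq)), None
            )
            if ref is None:
                raise ValidationError(
                    f"{group} slice {sid!r} has no {ref_freq:g} Hz point"
                )
            for f in frequencies:
                v = next(
                    (v for ff, v in values.items() if np.isclose(ff, f)), None
                )
                if v is None:
                    continue
                rows.append(
                    {
                        "group": group,
                        "slice_id": sid,
                        "frequency_hz": float(f),
                        "difference": v - ref,
                    }
                )
        if not rows:
            raise ValidationError(f"{group} curve has no points at {frequencies}")
        return rows

    per_slice = pd.DataFrame(
        slice_values(control, "control") + slice_values(kindled, "kindled")
    )
    group_means = (
        per_slice.groupby(["group", "frequency_hz"], as_index=False)["difference"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    gap = {}
    for f in frequencies:
        sel = per_slice["frequency_hz"] == float(f)
        c = per_slice[sel & (per_slice["group"] == "control")]["difference"].mean()
        k = per_slice[sel & (per_slice["group"] == "kindled")]["difference"].mean()
        gap[float(f)] = float(k - c)
    return FoldChangeContrast(
        region=control.region, per_slice=per_slice, group_means=group_means, gap=gap
    )


def fits_to_frame(fits: dict[str, SigmoidFit]) -> pd.DataFrame:
    rows = [
        {
            "region": region,
            "base": fit.base,
            "top": fit.top,
            "f_half": fit.f_half,
            "hill": fit.hill,
            "rss": fit.rss,
            "converged": fit.converged,
            "n_points": fit.n_points,
            "model": fit.model,
        }
        for region, fit in fits.items()
    ]
    return pd.DataFrame(rows)


def write_fits_csv(fits: dict[str, SigmoidFit], path: str | Path) -> Path:
    path = Path(path)
    fits_to_frame(fits).to_csv(path, index=False, float_format="%.9g")
    return path


__all__ = [
    "MIN_FIT_FREQUENCIES",
    "sigmoid",
    "log_sigmoid",
    "SigmoidFit",
    "IoCurve",
    "assemble_io_curve",
    "fit_sigmoid",
    "half_max_frequency",
    "FoldChangeContrast",
    "fold_change_contrast",
    "fits_to_frame",
    "write_fits_csv",
]
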