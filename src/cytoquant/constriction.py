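"""Contractile-ring constriction kinetics from diameter traces.

A ring-closure trace d(t) typically shows a plateau (metaphase/anaphase
onset), a roughly constant-rate constriction phase, and a slow tail as the
ring compacts into the midbody.  The constriction rate is estimated as the
slope of an ordinary least-squares line d = alpha + beta*t over four
consecutive timepoints inside the constant phase, taken as ~80-40% of the
initial diameter; the fit is accepted only if R^2 exceeds a threshold
(default 0.95), otherwise the trace is flagged as having no constant phase.

Onset (t0) is the frame prior to the first detectable change in diameter;
traces are normalized to d(t0) for plotting and group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DiameterTrace:
    """Timed ring diameters for one division.

    ``t_min`` must be strictly increasing and uniformly sampled (within 1%),
    ``d_um`` positive, and the trace at least 6 frames long.
    """

    t_min: np.ndarray
    d_um: np.ndarray
    sample_id: str = "trace"

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.d_um = np.asarray(self.d_um, dtype=float)
        if self.t_min.shape != self.d_um.shape or self.t_min.ndim != 1:
            raise ValueError("t_min and d_um must be equal-length 1D arrays")
        if len(self.t_min) < 6:
            raise ValueError("trace must have at least 6 frames")
        dt = np.diff(self.t_min)
        if np.any(dt <= 0):
            raise ValueError("t_min must be strictly increasing")
        if np.ptp(dt) > 0.01 * dt.mean():
            raise ValueError("sampling must be uniform within 1%")
        if np.any(self.d_um <= 0):
            raise ValueError("diameters must be positive")

    def __len__(self) -> int:
        return len(self.t_min)

    @property
    def dt_min(self) -> float:
        return float(np.diff(self.t_min).mean())


@dataclass
class ConstrictionFit:
    """A fitted constant-phase window.

    ``beta_um_per_min`` keeps the sign of the slope (negative for a closing
    ring); ``rate_um_per_min`` is its magnitude.
    """

    t0_index: int
    d_t0_um: float
    window: tuple[int, int, int, int]
    alpha_um: float
    beta_um_per_min: float
    r2: float
    normalized_trace: np.ndarray = field(repr=False)

    @property
    def rate_um_per_min(self) -> float:
        return abs(self.beta_um_per_min)


def traces_to_csv(traces: list[DiameterTrace], path) -> None:
    """Write traces as long-format CSV (sample_id, t_min, d_um)."""
    pd.concat(
        [
            pd.DataFrame({"sample_id": tr.sample_id, "t_min": tr.t_min, "d_um": tr.d_um})
            for tr in traces
        ],
        ignore_index=True,
    ).to_csv(path, index=False)


def traces_from_csv(path) -> list[DiameterTrace]:
    """Read long-format trace CSV back into :class:`DiameterTrace` objects."""
    df = pd.read_csv(path)
    return [
        DiameterTrace(
            t_min=sub["t_min"].to_numpy(),
            d_um=sub["d_um"].to_numpy(),
            sample_id=str(sid),
        )
        for sid, sub in df.groupby("sample_id", sort=True)
    ]


def detect_onset(trace: DiameterTrace, delta_rel: float = 0.05, persist: int = 3) -> int:
    """Index of the frame prior to the first sustained diameter decrease.

    A frame f marks constriction when d[f] has dropped below
    ``(1 - delta_rel) * d[0]`` and the trace is non-increasing — within a
    noise tolerance of ``delta_rel * d[0] / 2`` — over the next ``persist``
    frames.  Returns ``f - 1`` (the last plateau frame).

    Raises
    ------
    ValueError
        If no such frame exists ("no constriction detected").
    """
    d = trace.d_um
    drop_level = (1.0 - delta_rel) * d[0]
    tol = delta_rel * d[0] / 2.0
    for f in range(1, len(d)):
        if d[f] >= drop_level:
            continue
        upto = min(len(d), f + persist + 1)
        if np.all(np.diff(d[f - 1 : upto]) <= tol):
            return f - 1
    raise ValueError(f"no constriction detected in trace {trace.sample_id!r}")


def normalize_trace(trace: DiameterTrace, t0_index: int) -> np.ndarray:
    """Diameters normalized to the onset diameter; exactly 1 at t0."""
    if not 0 <= t0_index < len(trace):
        raise ValueError("t0_index out of range")
    d_t0 = trace.d_um[t0_index]
    if d_t0 == 0:
        raise ValueError("diameter at t0 is zero; cannot normalize")
    out = trace.d_um / d_t0
    out[t0_index] = 1.0
    return out


def _ols_line(t: np.ndarray, d: np.ndarray) -> tuple[float, float, float]:
    """Least-squares d = alpha + beta*t with R^2; R^2 is NaN for a flat window."""
    beta, alpha = np.polyfit(t, d, 1)
    resid = d - (alpha + beta * t)
    sstot = float(np.sum((d - d.mean()) ** 2))
    if sstot == 0.0:
        return float(alpha), float(beta), float("nan")
    r2 = 1.0 - float(np.sum(resid**2)) / sstot
    return float(alpha), float(beta), r2


def fit_constant_phase(
    trace: DiameterTrace,
    t0_index: int,
    band: tuple[float, float] = (0.40, 0.80),
    r2_threshold: float = 0.95,
) -> ConstrictionFit:
    """Fit the constant constriction phase on 4 consecutive timepoints.

    Candidate windows are every run of 4 consecutive post-onset frames whose
    normalized diameters all lie in ``band`` (endpoints inclusive).  Each
    window gets an OLS fit of the *absolute* diameter on time; windows with
    R^2 above ``r2_threshold`` qualify and the max-R^2 window wins (earliest
    on ties).  Flat windows (zero diameter variance) have undefined R^2 and
    are skipped.

    Raises
    ------
    ValueError
        "no constant phase in band" when no window lies in the band;
        "R2 threshold not met" when windows exist but none fits linearly
        (the trace should then be flagged/excluded, not forced).
    """
    lo, hi = band
    norm = normalize_trace(trace, t0_index)
    candidates = [
        i
        for i in range(t0_index + 1, len(trace) - 3)
        if np.all((norm[i : i + 4] >= lo) & (norm[i : i + 4] <= hi))
    ]
    if not candidates:
        raise ValueError(
            f"no constant phase in band [{lo}, {hi}] for trace {trace.sample_id!r}"
        )
    best = None
    for i in candidates:
        t_w = trace.t_min[i : i + 4]
        d_w = trace.d_um[i : i + 4]
        alpha, beta, r2 = _ols_line(t_w, d_w)
        if not np.isfinite(r2) or r2 <= r2_threshold:
            continue
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, i, alpha, beta)
    if best is None:
        raise ValueError(
            f"R2 threshold not met (> {r2_threshold}) for trace {trace.sample_id!r}"
        )
    r2, i, alpha, beta = best
    return ConstrictionFit(
        t0_index=t0_index,
        d_t0_um=float(trace.d_um[t0_index]),
        window=(i, i + 1, i + 2, i + 3),
        alpha_um=alpha,
        beta_um_per_min=beta,
        r2=r2,
        normalized_trace=norm,
    )


def mean_trace_with_sd(
    normalized_traces: list[np.ndarray],
    t0_indices: list[int],
    dt_min: float,
) -> pd.DataFrame:
    """Pointwise mean +/- SD of normalized traces aligned at t0.

    Traces are re-indexed to time relative to onset (t = 0 at t0) and
    aggregated per timepoint over whichever traces are present there.  SD is
    the sample standard deviation and is reported as missing where fewer than
    two traces overlap.

    Returns a frame with columns ``t_min, mean, sd, n``.
    """
    if len(normalized_traces) != len(t0_indices):
        raise ValueError("one t0 index per trace required")
    if not normalized_traces:
        raise ValueError("no traces supplied")
    frames: dict[int, list[float]] = {}
    for norm, t0 in zip(normalized_traces, t0_indices):
        for j, v in enumerate(np.asarray(norm, dtype=float)):
            frames.setdefault(j - t0, []).append(float(v))
    rows = []
    for rel in sorted(frames):
        vals = np.array(frames[rel])
        sd = float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan
        rows.append((rel * dt_min, float(vals.mean()), sd, len(vals)))
    return pd.DataFrame(rows, columns=["t_min", "mean", "sd", "n"])
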