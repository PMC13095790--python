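"""Dose-volume histogram containers and dose metrics.

A differential DVH is a list of (dose-bin, volume-fraction) pairs: bin doses
are left edges in Gy (or Gy(RBE) for proton plans with the constant RBE of
1.1 already applied upstream), ascending, and the volume fractions sum to
one.  A cumulative DVH gives, for each dose threshold, the volume fraction
receiving at least that dose; it starts at 1 at 0 Gy and is non-increasing.
All metrics (mean dose, gEUD, D_n%, V_nGy) operate on the differential form.

The generalized equivalent uniform dose reduces a heterogeneous dose
distribution to a single scalar via the power-law mean

    gEUD(a) = (sum_i v_i * D_i**a) ** (1/a)

where ``a`` is the volume-effect exponent: ``a = 1`` gives the mean dose,
large ``a`` approaches the maximum dose (serial-organ behaviour), and
``a < 1`` weights toward low doses (parallel organs).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ValidationError

__all__ = [
    "DifferentialDVH",
    "CumulativeDVH",
    "FractionationParams",
    "cumulative_to_differential",
    "differential_to_cumulative",
    "mean_dose",
    "geud",
    "dose_at_hottest_fraction",
    "volume_above",
    "lq_convert",
    "read_dvh_csv",
    "write_dvh_csv",
]

_SUM_TOL = 1e-9


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class DifferentialDVH:
    """Differential DVH: left bin edges (Gy) with volume fractions summing to 1."""

    doses: np.ndarray
    fractions: np.ndarray

    def __post_init__(self):
        doses = _as_float_array(self.doses, "doses")
        fractions = _as_float_array(self.fractions, "fractions")
        if doses.shape != fractions.shape:
            raise ValidationError("doses and fractions must have equal length")
        if np.any(doses < 0):
            raise ValidationError("bin doses must be >= 0")
        if np.any(np.diff(doses) <= 0):
            raise ValidationError("bin doses must be strictly increasing")
        if np.any(fractions < 0):
            raise ValidationError("volume fractions must be >= 0")
        total = float(fractions.sum())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValidationError(
                f"volume fractions must sum to 1 (got {total:.12g})"
            )
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "fractions", fractions)

    @property
    def max_dose(self) -> float:
        nz = self.doses[self.fractions > 0]
        return float(nz.max()) if nz.size else 0.0

    @property
    def min_dose(self) -> float:
        nz = self.doses[self.fractions > 0]
        return float(nz.min()) if nz.size else 0.0

    def scaled(self, factor: float) -> "DifferentialDVH":
        """Return a copy with every bin dose multiplied by ``factor`` > 0."""
        if factor <= 0:
            raise ValidationError("dose scale factor must be positive")
        return DifferentialDVH(self.doses * factor, self.fractions.copy())


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: volume fraction at-or-above each ascending dose threshold."""

    thresholds: np.ndarray
    fractions_at_or_above: np.ndarray

    def __post_init__(self):
        thr = _as_float_array(self.thresholds, "thresholds")
        frac = _as_float_array(self.fractions_at_or_above, "fractions_at_or_above")
        if thr.shape != frac.shape:
            raise ValidationError("thresholds and fractions must have equal length")
        if np.any(thr < 0) or np.any(np.diff(thr) <= 0):
            raise ValidationError("thresholds must be >= 0 and strictly increasing")
        if thr[0] != 0.0:
            raise ValidationError("cumulative DVH must start at dose 0")
        if abs(frac[0] - 1.0) > _SUM_TOL:
            raise ValidationError("cumulative DVH must start at volume fraction 1")
        if np.any(frac < -_SUM_TOL) or np.any(frac > 1 + _SUM_TOL):
            raise ValidationError("cumulative fractions must lie in [0, 1]")
        if np.any(np.diff(frac) > _SUM_TOL):
            raise ValidationError("cumulative fractions must be non-increasing")
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "fractions_at_or_above", np.clip(frac, 0.0, 1.0))


@dataclass(frozen=True)
class FractionationParams:
    """Fractionation schedule for linear-quadratic dose conversion.

    ``alpha_beta`` is the tissue alpha/beta ratio in Gy; 10 Gy is the
    conventional value for acute effects and is the default here.
    """

    dose_per_fraction: float
    n_fractions: int
    alpha_beta: float = 10.0

    def __post_init__(self):
        if self.dose_per_fraction <= 0 or self.n_fractions <= 0 or self.alpha_beta <= 0:
            raise ValidationError("fractionation parameters must be strictly positive")


def cumulative_to_differential(cdvh: CumulativeDVH) -> DifferentialDVH:
    """Difference a cumulative DVH into bins; total volume is conserved.

    The drop in cumulative volume across ``[t_k, t_{k+1})`` becomes the
    fraction of the bin at left edge ``t_k``; volume still at-or-above the
    last threshold is assigned to that final threshold.
    """
    frac = cdvh.fractions_at_or_above
    drops = np.append(-np.diff(frac), frac[-1])
    keep = drops > 0
    if not np.any(keep):
        # fully degenerate: everything at dose 0
        return DifferentialDVH(np.array([0.0]), np.array([1.0]))
    doses = cdvh.thresholds[keep]
    fractions = drops[keep]
    return DifferentialDVH(doses, fractions / fractions.sum())


def differential_to_cumulative(dvh: DifferentialDVH) -> CumulativeDVH:
    """Inverse of :func:`cumulative_to_differential` (round-trip identity)."""
    tail = np.cumsum(dvh.fractions[::-1])[::-1]
    tail = tail / tail[0]  # guard the 1-ulp cumsum drift at the total
    if dvh.doses[0] == 0.0:
        thresholds = dvh.doses
        fractions = tail
    else:
        thresholds = np.concatenate([[0.0], dvh.doses])
        fractions = np.concatenate([[1.0], tail])
    return CumulativeDVH(thresholds, np.clip(fractions, 0.0, 1.0))


def mean_dose(dvh: DifferentialDVH) -> float:
    """Volume-weighted mean dose, sum_i v_i D_i, in Gy."""
    return float(np.dot(dvh.fractions, dvh.doses))


def geud(dvh: DifferentialDVH, a: float) -> float:
    """Generalized equivalent uniform dose at volume-effect exponent ``a``.

    Evaluated in log space (log-sum-exp) so that large exponents, e.g. the
    serial-organ regime a ~ 20 where D_i**a overflows naive accumulation,
    stay finite.  ``a = 0`` (the geometric-mean limit) is not defined here,
    and negative ``a`` is incompatible with zero-dose bins.
    """
    if a == 0:
        raise ValidationError("geud is undefined at a = 0")
    pos = dvh.fractions > 0
    doses = dvh.doses[pos]
    fractions = dvh.fractions[pos]
    zero_dose = doses == 0
    if a < 0 and np.any(zero_dose):
        raise ValidationError("negative a is undefined with zero-dose bins")
    if np.all(zero_dose):
        return 0.0
    doses = doses[~zero_dose]
    fractions = fractions[~zero_dose]
    log_sum = logsumexp(np.log(fractions) + a * np.log(doses))
    return float(np.exp(log_sum / a))


def dose_at_hottest_fraction(dvh: DifferentialDVH, n_percent: float) -> float:
    """D_n%: minimum dose received by the hottest ``n_percent`` of the volume.

    When ``n_percent`` falls exactly on a cumulative-volume step the hotter
    bin's dose is returned (conservative convention).
    """
    if not 0 < n_percent <= 100:
        raise ValidationError("n_percent must lie in (0, 100]")
    tail = np.cumsum(dvh.fractions[::-1])[::-1]  # volume at-or-above each bin
    target = n_percent / 100.0
    ok = tail >= target - 1e-12
    # tail is non-increasing, so the hottest qualifying bin is the last True
    idx = np.nonzero(ok)[0]
    if idx.size == 0:  # float slack exhausted; whole volume qualifies at min
        return float(dvh.doses[0])
    return float(dvh.doses[idx[-1]])


def volume_above(dvh: DifferentialDVH, threshold_gy: float) -> float:
    """V_nGy: percent volume receiving strictly more than ``threshold_gy``."""
    if threshold_gy < 0:
        raise ValidationError("threshold must be >= 0")
    return 100.0 * float(dvh.fractions[dvh.doses > threshold_gy].sum())


def lq_convert(total_dose: float, fx: FractionationParams) -> dict:
    """Linear-quadratic conversions of a physical total dose.

    BED  = D * (1 + d / (alpha/beta))
    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)
    """
    d, ab = fx.dose_per_fraction, fx.alpha_beta
    return {
        "bed": total_dose * (1.0 + d / ab),
        "eqd2": total_dose * (d + ab) / (2.0 + ab),
    }


# --- CSV dialect -----------------------------------------------------------
# header `dose_gy,volume_fraction`, preceded by a metadata comment line
# `# type=cumulative|differential`

def write_dvh_csv(path, dvh) -> None:
    if isinstance(dvh, DifferentialDVH):
        kind, x, y = "differential", dvh.doses, dvh.fractions
    elif isinstance(dvh, CumulativeDVH):
        kind, x, y = "cumulative", dvh.thresholds, dvh.fractions_at_or_above
    else:
        raise ValidationError(f"unsupported DVH type {type(dvh).__name__}")
    lines = [f"# type={kind}", "dose_gy,volume_fraction"]
    lines += [f"{xi:.10g},{yi:.10g}" for xi, yi in zip(x, y)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dvh_csv(path):
    """Read the DVH CSV dialect; the metadata comment selects the type."""
    with open(path) as fh:
        text = fh.read()
    kind = None
    data_lines = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            meta = line.lstrip("#").strip()
            if meta.startswith("type="):
                kind = meta.split("=", 1)[1].strip()
            continue
        data_lines.append(line)
    if kind not in ("cumulative", "differential"):
        raise ValidationError(f"missing or unknown DVH type metadata in {path}")
    import pandas as pd

    frame = pd.read_csv(_io.StringIO("\n".join(data_lines)))
    if list(frame.columns) != ["dose_gy", "volume_fraction"]:
        raise ValidationError(f"unexpected DVH CSV header in {path}")
    x = frame["dose_gy"].to_numpy(float)
    y = frame["volume_fraction"].to_numpy(float)
    if kind == "differential":
        return DifferentialDVH(x, y / y.sum())
    return CumulativeDVH(x, y)
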