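"""Monte Carlo estimation of the dose to circulating blood.

Circulating lymphocytes are not a fixed organ: blood parcels move through
the vasculature and accumulate dose only while they happen to sit inside an
irradiated organ during beam-on.  This module models that with a renewal
Markov chain over a small set of blood-pool compartments (aorta, heart,
lungs, ..., plus an out-of-field remainder):

* a particle (blood parcel) starts each fraction in a compartment drawn
  from the compartmental blood-volume fractions;
* it dwells there for an exponential time with the compartment's mean
  transit time, then jumps to a compartment again drawn from the
  blood-volume fractions (renewal approximation — no organ-specific
  transfer topology);
* during the beam-on window [0, BDT] of each fraction, a particle residing
  in organ *o* accrues dose at rate (voxel dose)/BDT, where the voxel dose
  is one draw from *o*'s per-fraction differential DVH per organ visit per
  fraction (a parcel traverses one spatial path per pass);
* doses accumulate over the fractions included in the analysis; the output
  is the histogram of per-particle cumulative doses.

The renewal routing is the single largest approximation relative to
physiologic circulation models with explicit transfer paths; its stationary
occupancy is f_i * tau_i / sum_j f_j tau_j rather than f_i unless transit
times are proportional across compartments.  See docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dvh import DifferentialDVH, mean_dose, geud, dose_at_hottest_fraction, volume_above
from .errors import ValidationError

__all__ = [
    "Compartment",
    "BloodFlowModel",
    "DeliverySchedule",
    "BloodDoseResult",
    "simulate_blood_dvh",
    "blood_metrics",
]

_FRACTION_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Compartment:
    name: str
    blood_fraction: float
    transit_s: float


@dataclass(frozen=True)
class BloodFlowModel:
    """Blood-pool partition: volume fractions and mean transit times."""

    compartments: tuple

    def __post_init__(self):
        comps = tuple(self.compartments)
        if not comps:
            raise ValidationError("flow model needs at least one compartment")
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise ValidationError("compartment names must be unique")
        fracs = np.array([c.blood_fraction for c in comps], float)
        transits = np.array([c.transit_s for c in comps], float)
        if np.any(fracs <= 0):
            raise ValidationError("blood volume fractions must be > 0")
        if abs(fracs.sum() - 1.0) > _FRACTION_SUM_TOL:
            raise ValidationError(
                f"blood volume fractions must sum to 1 (got {fracs.sum():.12g})"
            )
        if np.any(transits <= 0):
            raise ValidationError("mean transit times must be > 0")
        object.__setattr__(self, "compartments", comps)

    @property
    def names(self) -> list:
        return [c.name for c in self.compartments]

    @property
    def blood_fractions(self) -> np.ndarray:
        return np.array([c.blood_fraction for c in self.compartments], float)

    @property
    def transit_times(self) -> np.ndarray:
        return np.array([c.transit_s for c in self.compartments], float)

    def stationary_occupancy(self) -> np.ndarray:
        """Long-run fraction of time in each compartment under renewal routing."""
        w = self.blood_fractions * self.transit_times
        return w / w.sum()

    @classmethod
    def from_json(cls, path) -> "BloodFlowModel":
        with open(path) as fh:
            payload = json.load(fh)
        comps = [
            Compartment(c["name"], float(c["blood_fraction"]), float(c["transit_s"]))
            for c in payload["compartments"]
        ]
        return cls(tuple(comps))


@dataclass(frozen=True)
class DeliverySchedule:
    """Fractions included in the analysis and the beam-on time per fraction.

    ``n_fractions`` counts fractions up to the last lymphocyte-count
    measurement; ``bdt_s`` is the beam delivery time per fraction in
    seconds — the window during which in-field blood accrues dose.  No dose
    accrues between fractions.
    """

    n_fractions: int
    bdt_s: float

    def __post_init__(self):
        if self.n_fractions <= 0 or self.bdt_s <= 0:
            raise ValidationError("fraction count and beam time must be > 0")


@dataclass(frozen=True)
class BloodDoseResult:
    blood_dvh: DifferentialDVH
    mean_blood_dose: float
    n_particles: int
    seed: int
    particle_doses: np.ndarray  # raw per-particle cumulative doses, Gy


def _inverse_cdf_tables(flow: BloodFlowModel, organ_dvhs: Mapping[str, DifferentialDVH]):
    unknown = set(organ_dvhs) - set(flow.names)
    if unknown:
        raise ValidationError(
            f"organ DVHs reference compartments absent from the flow model: {sorted(unknown)}"
        )
    tables = []
    for name in flow.names:
        dvh = organ_dvhs.get(name)
        if dvh is None:
            tables.append(None)  # out-of-field: zero dose
        else:
            tables.append((dvh.doses, np.cumsum(dvh.fractions)))
    return tables


def simulate_blood_dvh(
    organ_dvhs: Mapping[str, DifferentialDVH],
    flow: BloodFlowModel,
    schedule: DeliverySchedule,
    n_particles: int = 100_000,
    time_step: float = 0.1,
    seed: int = 0,
    bin_width: float = 0.05,
) -> BloodDoseResult:
    """Simulate the cumulative dose distribution over circulating blood.

    ``organ_dvhs`` maps compartment names to *per-fraction* differential
    DVHs; compartments without an entry receive zero dose (out-of-field).
    Each fraction is simulated independently: the inter-fraction gap is
    hours to days while a full circulation takes about a minute, so the
    particle's location decorrelates completely between fractions and the
    start compartment is redrawn from the blood-volume fractions.

    The integrator is event-driven (exponential dwell times are sampled
    exactly), so ``time_step`` does not control accuracy; it is validated
    for interface compatibility only.  Results are bit-reproducible for a
    fixed (seed, configuration) pair.
    """
    if n_particles <= 0:
        raise ValidationError("n_particles must be > 0")
    if time_step <= 0:
        raise ValidationError("time_step must be > 0")
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")

    tables = _inverse_cdf_tables(flow, organ_dvhs)
    routing_cdf = np.cumsum(flow.blood_fractions)
    transits = flow.transit_times
    bdt = schedule.bdt_s

    rng = np.random.default_rng(seed)
    doses = np.zeros(n_particles)

    for _ in range(schedule.n_fractions):
        alive = np.arange(n_particles)
        comp = np.searchsorted(routing_cdf, rng.random(n_particles), side="right")
        comp = np.minimum(comp, len(transits) - 1)
        t = np.zeros(n_particles)
        while alive.size:
            c = comp[alive]
            dwell = rng.exponential(transits[c])
            end = t[alive] + dwell
            overlap = np.minimum(end, bdt) - t[alive]
            # one voxel-dose draw per particle-visit; the uniform is drawn
            # for every visit (also out-of-field) to keep the random stream
            # independent of which compartments carry dose
            u = rng.random(alive.size)
            voxel = np.zeros(alive.size)
            for ci in np.unique(c):
                table = tables[ci]
                if table is None:
                    continue
                sel = c == ci
                bin_doses, cdf = table
                idx = np.minimum(
                    np.searchsorted(cdf, u[sel], side="right"), len(bin_doses) - 1
                )
                voxel[sel] = bin_doses[idx]
            doses[alive] += voxel * overlap / bdt
            t[alive] = end
            survivors = end < bdt
            alive = alive[survivors]
            if alive.size:
                nxt = np.searchsorted(routing_cdf, rng.random(alive.size), side="right")
                comp[alive] = np.minimum(nxt, len(transits) - 1)

    blood_dvh = _histogram_dvh(doses, bin_width)
    return BloodDoseResult(
        blood_dvh=blood_dvh,
        mean_blood_dose=float(doses.mean()),
        n_particles=n_particles,
        seed=seed,
        particle_doses=doses,
    )


def _histogram_dvh(doses: np.ndarray, bin_width: float) -> DifferentialDVH:
    top = float(doses.max())
    if top <= 0:
        return DifferentialDVH(np.array([0.0]), np.array([1.0]))
    n_bins = int(np.floor(top / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(doses, bins=edges)
    fractions = counts / counts.sum()
    return DifferentialDVH(edges[:-1], fractions)


_D_PERCENT_GRID = (10, 20, 30, 40, 50, 60, 70, 80, 90)
_V_GY_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5)


def blood_metrics(result: BloodDoseResult, a: float) -> dict:
    """Standard blood-DVH summary: gEUD(a), D_10..90%, V_1..3.5Gy, mean dose."""
    dvh = result.blood_dvh
    return {
        "mean_gy": mean_dose(dvh),
        "geud_gy": geud(dvh, a) if dvh.max_dose > 0 else 0.0,
        "d_percent_gy": {n: dose_at_hottest_fraction(dvh, n) for n in _D_PERCENT_GRID},
        "v_gy_percent": {t: volume_above(dvh, t) for t in _V_GY_GRID},
    }
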