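"""Reporter-assay quantification: Miller units and heat-induction profiles.

Miller units follow the standard convention

    M.U. = scale * (A420 - correction * A550) / (time_min * volume_mL * OD600)

with ``scale`` = 1000 and ``correction`` = 1.75 by default (both
configurable, since published protocols vary).  Heat induction is the ratio
of mean Miller units at an elevated temperature to the mean at the reference
temperature (25 °C by default); its standard error uses first-order
propagation of the per-temperature standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class AssayMeasurement:
    construct_id: str
    temperature: float
    replicate: int
    A420: float
    OD600: float
    time: float            # minutes
    volume: float          # mL
    A550: float = 0.0

    def __post_init__(self):
        if self.OD600 <= 0:
            raise AssayError("OD600 must be positive")
        if self.time <= 0:
            raise AssayError("time must be positive")
        if self.volume <= 0:
            raise AssayError("volume must be positive")


@dataclass(frozen=True)
class MillerResult:
    construct_id: str
    temperature: float
    replicate: int
    miller_units: float

    def __post_init__(self):
        if not math.isfinite(self.miller_units):
            raise AssayError("Miller units must be finite")


@dataclass(frozen=True)
class HeatInductionProfile:
    construct_id: str
    reference_temp: float
    mean_mu: tuple[tuple[float, float], ...]        # temperature -> mean M.U.
    sd_mu: tuple[tuple[float, float], ...]          # temperature -> SD
    n_reps: tuple[tuple[float, int], ...]
    induction: tuple[tuple[float, float], ...]      # temperature -> ratio vs reference
    induction_se: tuple[tuple[float, float], ...]

    def as_dicts(self):
        return (dict(self.mean_mu), dict(self.sd_mu), dict(self.induction),
                dict(self.induction_se))


def miller_units(m: AssayMeasurement, correction: float = 1.75,
                 scale: float = 1000.0) -> MillerResult:
    mu = scale * (m.A420 - correction * m.A550) / (m.time * m.volume * m.OD600)
    return MillerResult(m.construct_id, m.temperature, m.replicate, mu)


def heat_induction_profile(results: list[MillerResult],
                           reference_temp: float = 25.0) -> HeatInductionProfile:
    """Per-temperature mean/SD and induction ratios relative to the reference.

    Induction is the ratio of means; SE(ratio) is propagated to first order:
    SE(r)^2 = r^2 * ((SE_T/mean_T)^2 + (SE_ref/mean_ref)^2).
    """
    if not results:
        raise AssayError("no results")
    cid = results[0].construct_id
    by_temp: dict[float, list[float]] = {}
    for r in results:
        if r.construct_id != cid:
            raise AssayError("profile mixes constructs")
        by_temp.setdefault(r.temperature, []).append(r.miller_units)
    if reference_temp not in by_temp:
        raise AssayError(f"missing reference temperature {reference_temp}")

    mean, sd, se, nn = {}, {}, {}, {}
    for t, vals in by_temp.items():
        a = np.asarray(vals, dtype=float)
        mean[t] = float(a.mean())
        sd[t] = float(a.std(ddof=1)) if len(a) > 1 else 0.0
        se[t] = sd[t] / math.sqrt(len(a))
        nn[t] = len(a)
    ref = mean[reference_temp]
    if ref == 0:
        raise AssayError("zero mean at reference temperature")

    induction, ind_se = {}, {}
    for t in by_temp:
        r = mean[t] / ref
        induction[t] = r
        rel = 0.0
        if mean[t] != 0:
            rel += (se[t] / mean[t]) ** 2
        rel += (se[reference_temp] / ref) ** 2
        ind_se[t] = abs(r) * math.sqrt(rel)
    induction[reference_temp] = 1.0
    temps = sorted(by_temp)
    return HeatInductionProfile(
        construct_id=cid,
        reference_temp=reference_temp,
        mean_mu=tuple((t, mean[t]) for t in temps),
        sd_mu=tuple((t, sd[t]) for t in temps),
        n_reps=tuple((t, nn[t]) for t in temps),
        induction=tuple((t, induction[t]) for t in temps),
        induction_se=tuple((t, ind_se[t]) for t in temps),
    )


def replicate_ratios(results: list[MillerResult],
                     reference_temp: float = 25.0) -> dict[float, list[float]]:
    """Secondary output: replicate-wise ratios against the reference mean."""
    prof = heat_induction_profile(results, reference_temp)
    ref = dict(prof.mean_mu)[reference_temp]
    out: dict[float, list[float]] = {}
    for r in results:
        out.setdefault(r.temperature, []).append(r.miller_units / ref)
    return out


def classify_construct(profile: HeatInductionProfile, threshold: float = 2.0,
                       negative_control: HeatInductionProfile | None = None) -> str:
    """``thermometer`` iff max induction at a non-reference temperature meets
    the threshold (and exceeds the negative control at that temperature when
    a control profile is supplied); else ``no_induction``."""
    neg = dict(negative_control.induction) if negative_control else {}
    for t, r in profile.induction:
        if t == profile.reference_temp:
            continue
        if r >= threshold and r > neg.get(t, float("-inf")):
            return "thermometer"
    return "no_induction"


__all__ = [
    "AssayMeasurement", "MillerResult", "HeatInductionProfile",
    "miller_units", "heat_induction_profile", "replicate_ratios",
    "classify_construct", "AssayError",
]
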