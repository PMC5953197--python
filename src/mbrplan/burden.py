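"""Patient-level models: MCP, metastatic burden reduction, inverse solvers.

A patient is a set of bone lesions with volumes v_i (ml) and absorbed
doses D_i (Gy). Two summary models sit on top of the per-lesion TCP:

*   MCP (metastatic control probability): the product of all lesion TCPs,
    i.e. the probability that every lesion in the patient is eradicated.
*   MBR (metastatic burden reduction): the fraction of the baseline
    metastatic volume V = sum(v_i) belonging to lesions whose TCP reaches
    the eradication cutoff (TCP >= 0.95 by default; a lesion exactly at
    the cutoff counts as eradicated).

Both are driven by uniformly scaling the patient's *relative* distribution
of lesion doses. The patient mean absorbed dose (PMAD) is the arithmetic
mean of the lesion doses, so scaling the distribution by s moves the PMAD
to s * PMAD_delivered. The planning questions answered here are inverse
problems in s:

*   ``solve_pmad_for_mcp``: the PMAD at which MCP reaches a target
    (default 0.95), found by bisection on the scale factor.
*   ``solve_pmad_for_mbr``: the PMAD at which the burden reduction reaches
    a requested fraction. Because MBR is a step function of the scale with
    one jump per lesion (at s_i* = threshold_dose(v_i)/D_i), this is read
    off an analytically constructed step curve with no iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import NumericError, ValidationError
from .params import DOSE_MAX_GY, RadiobioParams
from .radbio import tcp, tcp_threshold_dose

__all__ = [
    "Lesion",
    "Patient",
    "MBRCurve",
    "PlanningResult",
    "mcp",
    "mbr",
    "mbr_curve",
    "solve_pmad_for_mcp",
    "solve_pmad_for_mbr",
    "plan_patient",
]

#: Relative tolerance on the bisection scale factor.
SCALE_RTOL = 1e-9

#: Flags attached to PlanningResult / MBRCurve.
FLAG_ZERO_DOSE = "zero_dose_lesion"
FLAG_MCP_UNREACHABLE = "mcp_target_unreachable"
FLAG_MBR_UNREACHABLE = "mbr_fraction_unreachable"
FLAG_DOSE_GUARD = "dose_above_guard"


@dataclass(frozen=True)
class Lesion:
    """A single bone lesion: volume (ml) and absorbed dose (Gy).

    The dose may be a delivered absolute dose or a relative value when the
    patient's dose distribution is used only as a shape to be scaled.
    """

    lesion_id: str
    volume: float
    dose: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.volume) and self.volume > 0):
            raise ValidationError(
                f"lesion {self.lesion_id!r}: volume must be strictly positive, got {self.volume!r}"
            )
        if not (math.isfinite(self.dose) and self.dose >= 0):
            raise ValidationError(
                f"lesion {self.lesion_id!r}: dose must be non-negative, got {self.dose!r}"
            )


@dataclass(frozen=True)
class Patient:
    """An ordered collection of lesions belonging to one patient."""

    patient_id: str
    lesions: tuple[Lesion, ...]

    def __post_init__(self) -> None:
        lesions = tuple(self.lesions)
        object.__setattr__(self, "lesions", lesions)
        if len(lesions) == 0:
            raise ValidationError(f"patient {self.patient_id!r}: at least one lesion required")

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([l.volume for l in self.lesions], dtype=float)

    @property
    def doses(self) -> np.ndarray:
        return np.array([l.dose for l in self.lesions], dtype=float)

    @property
    def burden(self) -> float:
        """Baseline metastatic burden V = sum of lesion volumes (ml)."""
        return float(self.volumes.sum())

    @property
    def pmad(self) -> float:
        """Patient mean absorbed dose: arithmetic mean of lesion doses (Gy)."""
        return float(self.doses.mean())

    def scaled(self, scale: float) -> "Patient":
        """A copy with every lesion dose multiplied by ``scale``."""
        return Patient(
            self.patient_id,
            tuple(replace(l, dose=l.dose * scale) for l in self.lesions),
        )


@dataclass(frozen=True)
class MBRCurve:
    """Right-continuous non-decreasing step curve PMAD -> burden reduction.

    ``breakpoints`` holds (pmad_gy, mbr) pairs with strictly increasing
    pmad and strictly increasing mbr; the curve value at a query PMAD is
    the mbr of the last breakpoint at or below it (0 before the first,
    unless a lesion is eradicated at zero dose, in which case the curve
    starts at that fraction). Lesions with zero dose never reach their
    threshold; such curves are capped below 1 and flagged.
    """

    patient_id: str
    breakpoints: tuple[tuple[float, float], ...]
    baseline: float = 0.0  # MBR attained already at PMAD = 0
    flags: tuple[str, ...] = ()

    def pmad_values(self) -> np.ndarray:
        return np.array([p for p, _ in self.breakpoints], dtype=float)

    def mbr_values(self) -> np.ndarray:
        return np.array([m for _, m in self.breakpoints], dtype=float)

    def __call__(self, pmad) -> np.ndarray | float:
        """Evaluate the step curve (right-continuous) at PMAD value(s)."""
        scalar = np.isscalar(pmad)
        q = np.asarray(pmad, dtype=float)
        xs = self.pmad_values()
        ys = np.concatenate([[self.baseline], self.mbr_values()])
        idx = np.searchsorted(xs, q, side="right")
        out = ys[idx]
        return float(out) if scalar else out

    def pmad_for_fraction(self, fraction: float) -> float:
        """Smallest breakpoint PMAD achieving MBR >= fraction (inf if none)."""
        if not (0.0 < fraction <= 1.0):
            raise ValidationError(f"fraction must lie in (0, 1], got {fraction!r}")
        if self.baseline >= fraction:
            return 0.0
        for pmad_gy, value in self.breakpoints:
            if value >= fraction:
                return pmad_gy
        return math.inf


@dataclass(frozen=True)
class PlanningResult:
    """Inverse-solver outputs for one patient."""

    patient_id: str
    pmad_delivered: float
    scale_mcp: float = math.nan
    pmad_mcp: float = math.nan
    pmad_mbr: float = math.nan
    mbr_fraction: float = math.nan
    threshold_doses: tuple[float, ...] = ()
    flags: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# Forward models
# --------------------------------------------------------------------------

def _check_scale(scale: float) -> float:
    if not (math.isfinite(scale) and scale >= 0):
        raise ValidationError(f"scale must be finite and non-negative, got {scale!r}")
    return float(scale)


def mcp(patient: Patient, scale: float, params: RadiobioParams) -> float:
    """Metastatic control probability at a given dose scale factor.

    The product of the lesion TCPs evaluated at doses ``scale * D_i``:
    the probability that *all* lesions are eradicated. Non-decreasing in
    ``scale``; any lesion with TCP = 0 annihilates the product.
    """
    _check_scale(scale)
    tcps = tcp(scale * patient.doses, patient.volumes, params)
    return float(np.prod(tcps))


def _eradicated(patient: Patient, scale: float, params: RadiobioParams,
                cutoff: float) -> np.ndarray:
    """Boolean mask of lesions whose TCP reaches the cutoff at this scale."""
    tcps = np.asarray(tcp(scale * patient.doses, patient.volumes, params))
    return tcps >= cutoff


def mbr(patient: Patient, scale: float, params: RadiobioParams,
        cutoff: float | None = None) -> float:
    """Metastatic burden reduction at a given dose scale factor.

    ``MBR = 1 - sum(v_i * k_i) / V`` where ``k_i = 0`` (eradicated) iff the
    lesion's TCP at dose ``scale * D_i`` reaches the cutoff, else 1. Ranges
    from 0 (no lesion eradicated) to 1 (all eradicated); non-decreasing in
    ``scale``; takes at most N+1 distinct values.
    """
    _check_scale(scale)
    if cutoff is None:
        cutoff = params.tcp_cutoff
    killed = _eradicated(patient, scale, params, cutoff)
    v = patient.volumes
    return float(1.0 - v[~killed].sum() / v.sum())


# --------------------------------------------------------------------------
# Analytic step curve
# --------------------------------------------------------------------------

def lesion_threshold_doses(patient: Patient, params: RadiobioParams,
                           cutoff: float | None = None) -> np.ndarray:
    """Per-lesion absorbed doses at which TCP reaches the cutoff (Gy)."""
    return np.array(
        [tcp_threshold_dose(l.volume, params, cutoff) for l in patient.lesions],
        dtype=float,
    )


def mbr_curve(patient: Patient, params: RadiobioParams,
              cutoff: float | None = None) -> MBRCurve:
    """Analytic construction of the burden-reduction step curve.

    Each lesion is eradicated once the scale reaches
    ``s_i* = threshold_dose(v_i) / D_i``; sorting the s_i* and accumulating
    volume fractions yields the full curve, with breakpoints expressed on
    the PMAD axis (``pmad = s_i* * PMAD_delivered``). Ties (identical s_i*)
    merge into one breakpoint with the summed volume jump. Pointwise
    identical to a brute-force scan of :func:`mbr` over scale.

    Lesions with zero dose never reach threshold: the curve is capped below
    1 and flagged; lesions already controlled at zero dose (s_i* = 0) lift
    the curve's starting value instead of creating a breakpoint.
    """
    thresholds = lesion_threshold_doses(patient, params, cutoff)
    doses = patient.doses
    volumes = patient.volumes
    vtot = volumes.sum()
    pmad_delivered = patient.pmad

    flags: list[str] = []
    baseline = float(volumes[thresholds == 0.0].sum() / vtot)

    cold = (doses == 0.0) & (thresholds > 0.0)
    if np.any(cold):
        flags.append(FLAG_ZERO_DOSE)
        flags.append(FLAG_MBR_UNREACHABLE)

    active = (thresholds > 0.0) & (doses > 0.0)
    with np.errstate(divide="ignore"):
        scales = thresholds[active] / doses[active]
    order = np.argsort(scales, kind="stable")
    scales = scales[order]
    fracs = volumes[active][order] / vtot

    points: list[tuple[float, float]] = []
    cum = baseline
    i = 0
    while i < len(scales):
        j = i
        jump = 0.0
        while j < len(scales) and scales[j] == scales[i]:
            jump += fracs[j]
            j += 1
        cum += jump
        points.append((float(scales[i] * pmad_delivered), float(cum)))
        i = j
    if points and not np.any(cold):
        # All volume is accounted for: pin the final value to exactly 1 so
        # float summation drift cannot leave the curve at 1 - epsilon.
        points[-1] = (points[-1][0], 1.0)
    return MBRCurve(patient.patient_id, tuple(points), baseline=baseline,
                    flags=tuple(flags))


# --------------------------------------------------------------------------
# Inverse solvers
# --------------------------------------------------------------------------

def solve_pmad_for_mcp(patient: Patient, params: RadiobioParams,
                       target: float | None = None) -> PlanningResult:
    """PMAD at which the patient's MCP reaches ``target`` (default 0.95).

    Iteratively scales the relative dose distribution by a target dose
    scaling factor until MCP meets the target: the bracket ``[0, s_hi]`` is
    grown geometrically until MCP(s_hi) >= target, then bisected to a
    relative scale tolerance of 1e-9. MCP is monotone in the scale, so
    bisection converges unconditionally.

    Lesions receiving zero dose bound MCP away from 1; when the limiting
    MCP cannot reach the target the result carries an unreachable flag and
    non-finite doses instead of raising, so cohort runs do not abort.
    """
    if target is None:
        target = params.mcp_target
    if not (0.0 < target < 1.0):
        raise ValidationError(f"target must lie in (0, 1), got {target!r}")

    thresholds = lesion_threshold_doses(patient, params)
    pmad_delivered = patient.pmad
    flags: list[str] = []
    doses = patient.doses

    cold = (doses == 0.0) & (thresholds > 0.0)
    if np.any(cold):
        flags.append(FLAG_ZERO_DOSE)
        # MCP as scale -> inf is the product of the zero-dose lesions' TCP(0).
        limit = float(
            np.prod(tcp(np.zeros(int(cold.sum())), patient.volumes[cold], params))
        )
        if limit < target:
            flags.append(FLAG_MCP_UNREACHABLE)
            return PlanningResult(
                patient.patient_id, pmad_delivered, scale_mcp=math.inf,
                pmad_mcp=math.inf, threshold_doses=tuple(thresholds),
                flags=tuple(flags),
            )

    if mcp(patient, 0.0, params) >= target:
        scale = 0.0
    else:
        hi = 1.0
        for _ in range(200):
            if mcp(patient, hi, params) >= target:
                break
            hi *= 2.0
        else:
            raise NumericError(
                f"patient {patient.patient_id!r}: could not bracket MCP target {target}"
            )
        lo = 0.0
        while hi - lo > SCALE_RTOL * hi:
            mid = 0.5 * (lo + hi)
            if mcp(patient, mid, params) >= target:
                hi = mid
            else:
                lo = mid
        # Return the upper endpoint: the reported scale provably achieves
        # MCP >= target, so it dominates every lesion's threshold scale and
        # the ordering PMAD(MBR=1) <= PMAD(MCP target) holds exactly.
        scale = hi

    pmad_mcp = scale * pmad_delivered
    if scale * doses.max(initial=0.0) > DOSE_MAX_GY:
        flags.append(FLAG_DOSE_GUARD)
    return PlanningResult(
        patient.patient_id, pmad_delivered, scale_mcp=scale, pmad_mcp=pmad_mcp,
        threshold_doses=tuple(thresholds), flags=tuple(flags),
    )


def solve_pmad_for_mbr(patient: Patient, params: RadiobioParams,
                       fraction: float = 0.5) -> PlanningResult:
    """PMAD at which the burden reduction reaches ``fraction``.

    Defined as the infimum PMAD achieving MBR >= fraction on the
    right-continuous step curve, read directly off the analytic breakpoints
    of :func:`mbr_curve` — exact, no iteration. Unachievable fractions
    (zero-dose lesions capping the curve) yield a flagged infinite PMAD.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError(f"fraction must lie in (0, 1], got {fraction!r}")
    curve = mbr_curve(patient, params)
    pmad_f = curve.pmad_for_fraction(fraction)
    flags = list(curve.flags)
    if not math.isfinite(pmad_f):
        if FLAG_MBR_UNREACHABLE not in flags:
            flags.append(FLAG_MBR_UNREACHABLE)
    elif FLAG_MBR_UNREACHABLE in flags:
        flags.remove(FLAG_MBR_UNREACHABLE)  # requested fraction still reachable
    return PlanningResult(
        patient.patient_id, patient.pmad, pmad_mbr=pmad_f, mbr_fraction=fraction,
        threshold_doses=tuple(lesion_threshold_doses(patient, params)),
        flags=tuple(flags),
    )


def plan_patient(patient: Patient, params: RadiobioParams,
                 mbr_fraction: float = 0.5,
                 mcp_target: float | None = None) -> PlanningResult:
    """Full planning result: MCP solve and MBR solve combined."""
    r_mcp = solve_pmad_for_mcp(patient, params, mcp_target)
    r_mbr = solve_pmad_for_mbr(patient, params, mbr_fraction)
    flags = tuple(dict.fromkeys(r_mcp.flags + r_mbr.flags))
    return PlanningResult(
        patient.patient_id,
        patient.pmad,
        scale_mcp=r_mcp.scale_mcp,
        pmad_mcp=r_mcp.pmad_mcp,
        pmad_mbr=r_mbr.pmad_mbr,
        mbr_fraction=mbr_fraction,
        threshold_doses=r_mcp.threshold_doses,
        flags=flags,
    )
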