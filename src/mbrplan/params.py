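"""Radiobiological parameter set and flat key=value config files.

Defaults are the prostate-cancer parameter set used throughout the model
chain: linear radiosensitivity alpha = 0.15 Gy^-1, alpha/beta = 3.1 Gy,
sub-lethal damage repair rate mu = 0.46 h^-1, effective (physical +
biological) half-life 62 h, clonogenic cell density 3e6 cm^-3, and a
per-lesion eradication cutoff TCP >= 0.95 with a whole-patient control
target MCP = 0.95.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError

#: Guard on absorbed doses handled by the solvers (Gy). Doses beyond this are
#: physically meaningless for molecular radiotherapy and are flagged rather
#: than silently pushed through the exponentials.
DOSE_MAX_GY = 1.0e4

#: Survival fractions below this are clamped to zero (exp underflow floor).
SURVIVAL_FLOOR = 1.0e-300


@dataclass(frozen=True)
class RadiobioParams:
    """Immutable radiobiological parameter set.

    Attributes
    ----------
    alpha : float
        Linear radiosensitivity coefficient (Gy^-1); probability of cell
        death per unit dose via double-strand breaks.
    alpha_beta : float
        alpha/beta ratio (Gy), the dose at which linear and quadratic kill
        contributions are equal; low (~3 Gy) for prostate cancer.
    mu : float
        Sub-lethal damage repair rate constant (h^-1).
    t_half_eff : float
        Effective half-life of the radiopharmaceutical (h), combining
        physical decay and biological clearance.
    rho_c : float
        Clonogenic cell density (cm^-3).
    tcp_cutoff : float
        Per-lesion tumour control probability at which a lesion counts as
        eradicated in the burden-reduction model.
    mcp_target : float
        Whole-patient metastatic control probability target for the
        inverse dose solver.
    """

    alpha: float = 0.15
    alpha_beta: float = 3.1
    mu: float = 0.46
    t_half_eff: float = 62.0
    rho_c: float = 3.0e6
    tcp_cutoff: float = 0.95
    mcp_target: float = 0.95

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_beta", "mu", "t_half_eff", "rho_c"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")
        for name in ("tcp_cutoff", "mcp_target"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1), got {value!r}")

    @property
    def beta(self) -> float:
        """Quadratic radiosensitivity coefficient beta = alpha / (alpha/beta), Gy^-2."""
        return self.alpha / self.alpha_beta

    @property
    def lambda_eff(self) -> float:
        """Effective dose-rate decay constant ln(2)/t_half_eff, h^-1."""
        return math.log(2.0) / self.t_half_eff

    def replace(self, **changes: float) -> "RadiobioParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


_FIELD_NAMES = {f.name for f in dataclasses.fields(RadiobioParams)}


def load_params(path: str | Path) -> RadiobioParams:
    """Read a flat ``key=value`` parameter file.

    All keys are optional and default to the prostate-cancer set; blank
    lines and ``#`` comments are ignored. Unknown keys raise
    :class:`~mbrplan.errors.ValidationError`.
    """
    overrides: dict[str, float] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key=value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _FIELD_NAMES:
            raise ValidationError(f"{path}:{lineno}: unknown parameter {key!r}")
        try:
            overrides[key] = float(value.strip())
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: non-numeric value for {key!r}") from exc
    return RadiobioParams(**overrides)


def dump_params(params: RadiobioParams, path: str | Path) -> None:
    """Write a parameter set in the same flat key=value format."""
    lines = [
        f"{f.name}={getattr(params, f.name):.6g}"
        for f in dataclasses.fields(RadiobioParams)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
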