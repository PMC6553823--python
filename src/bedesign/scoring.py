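"""The multiplicative a-priori guide score.

For a guide with ``n`` scored (non-intended) genomic alignments the final
score is

    B = (prod_a  P_a * G_a) * A,          0 < B <= 1,

where P_a multiplies position-dependent mismatch penalties P_i over the
mismatches of alignment ``a`` (empty product = 1 for a perfect-match
off-target), G_a is a region multiplier (genic sites are worse, hence get
the smaller multiplier), and A reflects whether the editable base sits in
the editor's activity window.  All factors are multipliers in (0, 1], so an
optimal guide — in-window, no off-targets — scores exactly 1 and any
suboptimal feature strictly decreases B.

P_i derives from a third-degree polynomial fitted to a position-wise
mismatch-tolerance table (distance from the PAM vs mean tolerance).
Mismatches next to the PAM are poorly tolerated, so they earn the small
multiplier P_min; PAM-distal mismatches retain activity and earn up to
P_max.  For spacers shorter or longer than the 20-nt reference, distances
are rescaled onto the reference axis and the fitted curve interpolates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .offtarget import IntegrityError, OfftargetAlignment, mismatch_distances
from .registry import ConfigError, ContractViolation

__all__ = [
    "PenaltyModel",
    "ScoreBreakdown",
    "default_penalty_model",
    "fit_penalty_curve",
    "position_penalty",
    "alignment_penalty",
    "region_penalty",
    "score_guide",
]

# Defaults are configurable stand-ins chosen by requirement importance, not
# fitted to base-editing outcome data (none exists at library scale).
DEFAULT_P_MIN = 0.01
DEFAULT_P_MAX = 1.0
DEFAULT_G_GENIC = 0.5
DEFAULT_G_INTERGENIC = 0.9
DEFAULT_A_IN = 1.0
DEFAULT_A_OUT = 0.5
REFERENCE_GUIDE_LENGTH = 20


def _default_tolerance_table(
    p_min: float = DEFAULT_P_MIN, p_max: float = DEFAULT_P_MAX
) -> tuple[tuple[float, float], ...]:
    """Monotone synthetic mismatch-tolerance table over distances 1..20.

    Tolerance rises nonlinearly (quadratically here) from p_min adjacent to
    the PAM to p_max at the distal end, mimicking the shape of empirical
    Cas9 mismatch-tolerance profiles.
    """
    return tuple(
        (d, p_min + (p_max - p_min) * ((d - 1) / (REFERENCE_GUIDE_LENGTH - 1)) ** 2)
        for d in range(1, REFERENCE_GUIDE_LENGTH + 1)
    )


def fit_penalty_curve(table) -> tuple[float, float, float, float]:
    """Least-squares cubic through (distance, tolerance) pairs.

    Returns highest-degree-first coefficients, ``np.polyval`` convention.
    """
    xs = [float(d) for d, _ in table]
    ys = [float(t) for _, t in table]
    if len(set(xs)) < 4:
        raise ConfigError("penalty curve fit needs >= 4 distinct distances")
    return tuple(np.polyfit(xs, ys, 3).tolist())


@dataclass(frozen=True)
class PenaltyModel:
    """All numeric knobs of the scoring system; every one is configurable."""

    position_tolerance_table: tuple[tuple[float, float], ...] = field(
        default_factory=_default_tolerance_table
    )
    coefficients: tuple[float, float, float, float] | None = None
    P_min: float = DEFAULT_P_MIN
    P_max: float = DEFAULT_P_MAX
    G_g: float = DEFAULT_G_GENIC
    G_ig: float = DEFAULT_G_INTERGENIC
    A_in: float = DEFAULT_A_IN
    A_out: float = DEFAULT_A_OUT
    reference_guide_length: int = REFERENCE_GUIDE_LENGTH

    def __post_init__(self):
        for name in ("P_min", "P_max", "G_g", "G_ig", "A_in", "A_out"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name}={v} outside (0, 1]")
        if self.P_min > self.P_max:
            raise ConfigError("P_min must not exceed P_max")
        if self.G_g > self.G_ig:
            raise ConfigError(
                "G_g must not exceed G_ig (genic off-targets are worse and "
                "get the smaller multiplier)"
            )
        if self.coefficients is None:
            object.__setattr__(
                self, "coefficients", fit_penalty_curve(self.position_tolerance_table)
            )

    def to_dict(self) -> dict:
        return {
            "position_tolerance_table": [list(p) for p in self.position_tolerance_table],
            "P_min": self.P_min,
            "P_max": self.P_max,
            "G_g": self.G_g,
            "G_ig": self.G_ig,
            "A_in": self.A_in,
            "A_out": self.A_out,
            "reference_guide_length": self.reference_guide_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PenaltyModel":
        kw = dict(d)
        if "position_tolerance_table" in kw:
            kw["position_tolerance_table"] = tuple(
                tuple(p) for p in kw["position_tolerance_table"]
            )
        if "coefficients" in kw and kw["coefficients"] is not None:
            kw["coefficients"] = tuple(kw["coefficients"])
        return cls(**kw)


def default_penalty_model() -> PenaltyModel:
    return PenaltyModel()


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-guide score with its per-alignment factors."""

    guide_id: str
    n_alignments: int
    per_alignment: tuple[tuple[OfftargetAlignment, float, float], ...]
    A_applied: float
    B: float


# ---------------------------------------------------------------------------
# penalties
# ---------------------------------------------------------------------------

def position_penalty(distance: int, model: PenaltyModel, guide_length: int) -> float:
    """P_i for a mismatch at ``distance`` (1 = PAM-adjacent) from the PAM.

    Non-reference spacer lengths are handled by rescaling the distance onto
    the reference 20-nt axis before evaluating the fitted cubic; the value is
    clamped into [P_min, P_max].
    """
    if not (1 <= distance <= guide_length):
        raise ContractViolation(
            f"distance {distance} outside 1..{guide_length}"
        )
    x = distance * model.reference_guide_length / guide_length
    val = float(np.polyval(model.coefficients, x))
    return float(min(max(val, model.P_min), min(model.P_max, 1.0)))


def alignment_penalty(
    aln: OfftargetAlignment, model: PenaltyModel, guide_length: int, pam_side: str
) -> float:
    """P_a: product of P_i over an alignment's mismatches (empty product = 1)."""
    p = 1.0
    for d in mismatch_distances(aln, guide_length, pam_side):
        p *= position_penalty(d, model, guide_length)
    return p


def region_penalty(aln: OfftargetAlignment, model: PenaltyModel) -> float:
    """G_a: the genic or intergenic multiplier."""
    return model.G_g if aln.region == "genic" else model.G_ig


def score_guide(
    guide,
    alignments: list[OfftargetAlignment],
    model: PenaltyModel,
    guide_length: int,
    pam_side: str,
) -> ScoreBreakdown:
    """Final score B for one guide given its genomic alignments.

    The alignment coinciding with the guide's own protospacer is excluded
    from the product — otherwise no guide could ever reach the optimum of 1,
    being penalised by its own (genic) on-target site.
    """
    if not any(a.is_intended_target for a in alignments):
        raise IntegrityError(
            f"guide {guide.guide_id}: alignment list lacks the intended target"
        )
    scored = [a for a in alignments if not a.is_intended_target]
    per = []
    b = 1.0
    for a in scored:
        pa = alignment_penalty(a, model, guide_length, pam_side)
        ga = region_penalty(a, model)
        per.append((a, pa, ga))
        b *= pa * ga
    a_applied = model.A_in if guide.in_window else model.A_out
    b *= a_applied
    if not (0.0 < b <= 1.0) and not math.isclose(b, 0.0):
        raise IntegrityError(f"guide {guide.guide_id}: score {b} outside (0, 1]")
    return ScoreBreakdown(guide.guide_id, len(scored), tuple(per), a_applied, b)
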