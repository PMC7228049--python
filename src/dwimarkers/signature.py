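"""Diffusion-kurtosis signal model and the two-signature reference library.

The signature index locates a tissue's two-shell diffusion signal between two
reference *signatures*: signature B, a generic (gray-matter-like) mouse brain
tissue signal, and signature A, the same tissue after a moderate increase in
diffusion hindrance.  Both are normalized signal pairs at the two key shells
``Lb = 250`` and ``Hb = 1750`` s/mm².  The kurtosis signal representation

    S(b) / S0 = exp(-b D + (b D)^2 K / 6)

with diffusivity ``D`` (mm²/s) and excess kurtosis ``K`` (dimensionless) is
used to construct signatures and to parameterize synthetic tissue.  Over two
shells the representation is exactly invertible (two log-attenuations, two
unknowns), which :func:`fit_two_point` exploits in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SignatureError

__all__ = [
    "KurtosisParams",
    "SignatureLibrary",
    "kurtosis_signal",
    "fit_two_point",
    "make_signature",
    "default_library",
]

#: The two key b-values of the acquisition, s/mm².
KEY_LOW_B = 250.0
KEY_HIGH_B = 1750.0

#: Printed reference library: normalized signals of the two signatures at
#: (Lb, Hb).  A = moderately increased hindrance, B = generic brain tissue.
S_A = (0.858, 0.370)
S_B = (0.855, 0.317)


@dataclass(frozen=True)
class KurtosisParams:
    """Parameters of the kurtosis signal representation.

    Attributes
    ----------
    d:
        Diffusivity in mm²/s, strictly positive.
    k:
        Excess kurtosis, dimensionless.  Must exceed -3 so the signal stays
        well-behaved; use :meth:`validate_against` to additionally require a
        strictly decreasing signal over a b-range.
    """

    d: float
    k: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.d) or self.d <= 0:
            raise SignatureError(f"diffusivity must be positive, got {self.d}")
        if not np.isfinite(self.k) or self.k <= -3.0:
            raise SignatureError(f"kurtosis must exceed -3, got {self.k}")

    def validate_against(self, b_max: float) -> "KurtosisParams":
        """Require the signal to be strictly decreasing on [0, b_max].

        d/db log S = -D + b D² K / 3 < 0 on (0, b_max] iff K < 3 / (b_max D).
        """
        if self.k >= 3.0 / (b_max * self.d):
            raise SignatureError(
                f"kurtosis {self.k} too large: signal not decreasing up to b={b_max}"
            )
        return self

    def shifted(self, dd: float, dk: float) -> "KurtosisParams":
        return KurtosisParams(self.d + dd, self.k + dk)


def kurtosis_signal(params: KurtosisParams, b):
    """Normalized kurtosis-model signal S(b)/S0 at b-value(s) ``b`` (s/mm²)."""
    bd = np.asarray(b, dtype=float) * params.d
    return np.exp(-bd + bd * bd * params.k / 6.0)


def fit_two_point(
    s_lb: float, s_hb: float, lb: float = KEY_LOW_B, hb: float = KEY_HIGH_B
) -> KurtosisParams:
    """Invert the kurtosis representation from two shell signals, exactly.

    Writing y(b) = -ln S(b) = b D - (b D)² K / 6, the pair (y(Lb), y(Hb)) is
    linear in (D, c) with c = K D² / 6, giving the closed form

        D = (Hb² y_L - Lb² y_H) / (Lb Hb (Hb - Lb)),
        c = (Hb y_L - Lb y_H) / (Lb Hb (Hb - Lb)),   K = 6 c / D².

    Requires a hindered, decaying signal: 0 < s_hb < s_lb <= 1.
    """
    if not (0.0 < s_hb < s_lb <= 1.0):
        raise SignatureError(
            f"no hindered solution for signals ({s_lb}, {s_hb}): "
            "need 0 < S(Hb) < S(Lb) <= 1"
        )
    if not hb > lb > 0:
        raise SignatureError(f"need 0 < lb < hb, got ({lb}, {hb})")
    y_l = -np.log(s_lb)
    y_h = -np.log(s_hb)
    den = lb * hb * (hb - lb)
    d = (hb * hb * y_l - lb * lb * y_h) / den
    c = (hb * y_l - lb * y_h) / den
    if d <= 0:
        raise SignatureError(
            f"signals ({s_lb}, {s_hb}) imply non-positive diffusivity"
        )
    return KurtosisParams(d=float(d), k=float(6.0 * c / (d * d)))


def make_signature(
    base: KurtosisParams,
    hindrance_shift: tuple[float, float],
    lb: float = KEY_LOW_B,
    hb: float = KEY_HIGH_B,
) -> tuple[float, float]:
    """Signal pair at (Lb, Hb) for ``base`` shifted by ``(Δd, Δk)``.

    This is how a hindrance-change signature is synthesized from a measured
    baseline: shift the kurtosis parameters, evaluate the model at the two
    key shells.  The shifted parameters are validated (positive, decreasing
    signal up to Hb).
    """
    dd, dk = hindrance_shift
    shifted = base.shifted(dd, dk).validate_against(hb)
    return (
        float(kurtosis_signal(shifted, lb)),
        float(kurtosis_signal(shifted, hb)),
    )


def _mean_rule(s_a: float, s_b: float) -> float:
    return 0.5 * (s_a + s_b)


_SN_RULES = {"mean": _mean_rule}


@dataclass(frozen=True)
class SignatureLibrary:
    """Reference signal pairs S_A, S_B at (Lb, Hb) plus the S_N rule.

    The intermediate signal S_N(b) is produced per shell from S_A(b) and
    S_B(b) by the named rule (default: arithmetic mean).  The library also
    carries the derived relative-distance spans

        ΔX = dS_X(Hb) - dS_X(Lb),   dS_X(b) = [S_X(b) - S_N(b)] / S_N(b)

    for X in {A, B}, which are the denominators of the signature index.
    With the mean rule ΔA = -ΔB exactly.
    """

    s_a_lb: float = S_A[0]
    s_a_hb: float = S_A[1]
    s_b_lb: float = S_B[0]
    s_b_hb: float = S_B[1]
    lb: float = KEY_LOW_B
    hb: float = KEY_HIGH_B
    s_n_rule: str = "mean"
    s_n_lb: float = field(init=False)
    s_n_hb: float = field(init=False)
    delta_a: float = field(init=False)
    delta_b: float = field(init=False)

    def __post_init__(self) -> None:
        for name, v in (
            ("S_A(Lb)", self.s_a_lb),
            ("S_A(Hb)", self.s_a_hb),
            ("S_B(Lb)", self.s_b_lb),
            ("S_B(Hb)", self.s_b_hb),
        ):
            if not (0.0 < v <= 1.0):
                raise SignatureError(f"{name} = {v} outside (0, 1]")
        if self.s_n_rule not in _SN_RULES:
            raise SignatureError(f"unknown S_N rule {self.s_n_rule!r}")
        rule = _SN_RULES[self.s_n_rule]
        object.__setattr__(self, "s_n_lb", rule(self.s_a_lb, self.s_b_lb))
        object.__setattr__(self, "s_n_hb", rule(self.s_a_hb, self.s_b_hb))

        def rel(s, s_n):
            return (s - s_n) / s_n

        delta_a = rel(self.s_a_hb, self.s_n_hb) - rel(self.s_a_lb, self.s_n_lb)
        delta_b = rel(self.s_b_hb, self.s_n_hb) - rel(self.s_b_lb, self.s_n_lb)
        if delta_a == 0.0 or delta_b == 0.0:
            raise SignatureError("degenerate library: ΔA and ΔB must be nonzero")
        object.__setattr__(self, "delta_a", delta_a)
        object.__setattr__(self, "delta_b", delta_b)

    def to_dict(self) -> dict:
        return {
            "lb": self.lb,
            "hb": self.hb,
            "s_a_lb": self.s_a_lb,
            "s_a_hb": self.s_a_hb,
            "s_b_lb": self.s_b_lb,
            "s_b_hb": self.s_b_hb,
            "s_n_rule": self.s_n_rule,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureLibrary":
        return cls(**{k: d[k] for k in (
            "s_a_lb", "s_a_hb", "s_b_lb", "s_b_hb", "lb", "hb", "s_n_rule") if k in d})


def default_library() -> SignatureLibrary:
    """The shipped reference library (printed signature values, mean S_N rule)."""
    return SignatureLibrary()
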