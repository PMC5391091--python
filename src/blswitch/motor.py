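"""Downstream CheYp noise and flagellar-motor clockwise-bias statistics.

Active receptors phosphorylate the response regulator CheY; CheYp
decays (dephosphorylation by CheZ) at rate lambda_Y, so its mean tracks
the receptor activity,

    Y* = a_Y * Y0 * A0 * xi_a* / lambda_Y,

and receptor-activity fluctuations of standard deviation sigma_a
filtered through this first-order cascade produce CheYp fluctuations

    sigma_Y = a_Y * Y0 * A0 * sigma_a / sqrt(lambda_Y (lambda_Y + lambda_xi)),

where lambda_xi is the decay rate of the activity autocorrelation.  The
motor switches clockwise with the steep Hill bias P_CW(Y) =
Y^H/(Y^H + K_Y^H), so CheYp noise translates into a clockwise-bias
standard deviation delta_P_CW = (dP_CW/dY) sigma_Y, bounded above by
H sigma_Y/(4 K_Y).  Slow motor-level adaptation (rate lambda_m, adapted
Hill coefficient H_a) modifies this by a multiplicative square-root
correction that stays near one inside the motor's sensitive window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_core import ModelParams

__all__ = ["MotorParams", "cheYp_mean", "sigma_Y", "sigma_a_range",
           "cw_bias", "cw_bias_slope", "delta_pcw", "delta_pcw_bound",
           "y_max_sensitivity", "delta_pcw_adapted", "motor_report"]


@dataclass(frozen=True)
class MotorParams:
    """Phosphorylation-cascade and motor-response constants."""

    a_Y: float = 3.0          # CheY phosphorylation rate, 1/(uM s)
    Y0: float = 18.0          # total CheY, uM
    lambda_Y: float = 14.15   # CheYp dephosphorylation rate, 1/s
    K_Y: float = 3.0          # motor Hill constant, uM
    H: float = 20.0           # Hill coefficient, non-adapted motor
    H_a: float = 10.0         # Hill coefficient, adapted motor
    lambda_m: float = 0.0167  # motor adaptation rate, 1/s (~1 min)
    lambda_xi: float = 0.0    # activity-fluctuation decay rate, 1/s

    def __post_init__(self) -> None:
        for name in ("a_Y", "Y0", "lambda_Y", "K_Y", "lambda_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.lambda_xi < 0:
            raise ValueError("lambda_xi must be >= 0")
        if not (self.H > 1 and self.H_a > 1):
            raise ValueError("Hill coefficients must exceed 1")

    @classmethod
    def from_literature(cls, name: str, **overrides) -> "MotorParams":
        from .model_core import LITERATURE_SETS

        vals = LITERATURE_SETS[name.lower()]
        kw = dict(a_Y=vals["a_Y"], Y0=vals["Y0"], lambda_Y=vals["lambda_Y"])
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **kw) -> "MotorParams":
        return replace(self, **kw)


def _gain(motor: MotorParams, params: ModelParams) -> float:
    """Cascade gain a_Y * Y0 * A0 (uM/s per unit activity)."""
    return motor.a_Y * motor.Y0 * params.A0


def cheYp_mean(params: ModelParams, motor: MotorParams,
               xi_a_star: float) -> float:
    """Steady-state mean CheYp concentration Y* (uM).

    Assumes total CheY well above Y* so the phosphorylation flux is
    proportional to Y0.
    """
    return _gain(motor, params) * xi_a_star / motor.lambda_Y


def sigma_Y(sigma_a: float, motor: MotorParams,
            params: ModelParams) -> float:
    """Standard deviation of CheYp (uM) driven by activity noise.

    With lambda_xi = 0 this saturates the upper bound
    a_Y*Y0*A0*sigma_a/lambda_Y (slow receptor noise passes through the
    cascade unfiltered).
    """
    if sigma_a < 0:
        raise ValueError("sigma_a must be >= 0")
    lY = motor.lambda_Y
    return _gain(motor, params) * sigma_a / np.sqrt(lY * (lY + motor.lambda_xi))


def sigma_a_range(sigma_Y_low: float, sigma_Y_high: float,
                  motor: MotorParams, params: ModelParams,
                  ) -> tuple[float, float]:
    """Receptor-activity noise range implied by a measured sigma_Y range.

    Inverts the saturated cascade relation: sigma_a =
    sigma_Y * lambda_Y / (a_Y * Y0 * A0) at each endpoint.
    """
    if not 0 <= sigma_Y_low <= sigma_Y_high:
        raise ValueError("need 0 <= sigma_Y_low <= sigma_Y_high")
    g = _gain(motor, params)
    return (sigma_Y_low * motor.lambda_Y / g,
            sigma_Y_high * motor.lambda_Y / g)


def cw_bias(Y: float, motor: MotorParams) -> float:
    """Clockwise (tumble) probability of the motor at CheYp level Y."""
    if Y < 0:
        raise ValueError("Y must be >= 0")
    if Y == 0:
        return 0.0
    y = Y / motor.K_Y
    return 1.0 / (1.0 + y ** (-motor.H))


def cw_bias_slope(Y: float, motor: MotorParams, H: float | None = None,
                  ) -> float:
    """dP_CW/dY at CheYp level Y (1/uM), for Hill coefficient ``H``."""
    if H is None:
        H = motor.H
    y = Y / motor.K_Y
    if y == 0:
        return 0.0
    # log-space evaluation: y**(H-1) overflows for steep motors
    ln_y = np.log(y)
    ln_1pyH = H * ln_y + np.log1p(np.exp(-H * ln_y)) if ln_y > 0 \
        else np.log1p(np.exp(H * ln_y))
    return float(H / motor.K_Y * np.exp((H - 1.0) * ln_y - 2.0 * ln_1pyH))


def delta_pcw(sigma_Y_val: float, ybar: float, motor: MotorParams) -> float:
    """Std of the clockwise bias from CheYp noise at mean level ybar=Y/K_Y."""
    if sigma_Y_val < 0:
        raise ValueError("sigma_Y must be >= 0")
    return cw_bias_slope(ybar * motor.K_Y, motor) * sigma_Y_val


def delta_pcw_bound(sigma_Y_val: float, motor: MotorParams) -> float:
    """Upper bound H*sigma_Y/(4 K_Y) on the clockwise-bias std.

    The slope factor y^(H-1)/(1+y^H)^2 has a single maximum, 1/4 for
    H >> 1, at y = ((H-1)/(H+1))^(1/H).
    """
    return motor.H * sigma_Y_val / (4.0 * motor.K_Y)


def y_max_sensitivity(H: float) -> float:
    """Dimensionless CheYp level maximizing the Hill slope factor."""
    return ((H - 1.0) / (H + 1.0)) ** (1.0 / H)


def delta_pcw_adapted(sigma_Y_val: float, Y: float,
                      motor: MotorParams) -> float:
    """Clockwise-bias std including slow motor-level adaptation.

    delta_P_CW = sigma_Y * alpha_na * sqrt(1 - (lambda_m/lambda_Y) *
    (alpha_a/alpha_na) * (1 - alpha_a/alpha_na)), where alpha_na and
    alpha_a are the Hill slopes of the non-adapted (H) and adapted
    (H_a) response at the same Y.  Reduces to :func:`delta_pcw` when
    lambda_m = 0; the correction is negligible wherever the two slopes
    are comparable (the sensitive window of the motor).
    """
    a_na = cw_bias_slope(Y, motor, H=motor.H)
    a_a = cw_bias_slope(Y, motor, H=motor.H_a)
    if a_na == 0.0:
        return 0.0
    ratio = a_a / a_na
    bracket = 1.0 - (motor.lambda_m / motor.lambda_Y) * ratio * (1.0 - ratio)
    if bracket < 0:
        raise ArithmeticError(
            f"negative variance bracket ({bracket:.3g}); adaptation and "
            "cascade parameters are inconsistent")
    return sigma_Y_val * a_na * np.sqrt(bracket)


def motor_report(name_or_motor, params: ModelParams | None = None,
                 sigma_Y_range: tuple[float, float] = (0.09, 0.22),
                 xi_a_star: float | None = None) -> dict:
    """Summary dict: Y*, implied sigma_a range and bias-fluctuation bound.

    ``name_or_motor`` is a literature-set name ('morton-firth', 'rao',
    'kollmann') or a MotorParams; with a name, the matching receptor
    parameters are used unless ``params`` is given.
    """
    from .model_core import literature_params
    from .qssa import perfect_adaptation_xa

    if isinstance(name_or_motor, MotorParams):
        motor = name_or_motor
        if params is None:
            raise ValueError("params required with an explicit MotorParams")
    else:
        lit_params, _ = literature_params(name_or_motor)
        motor = MotorParams.from_literature(name_or_motor)
        params = params if params is not None else lit_params
    if xi_a_star is None:
        xi_a_star = perfect_adaptation_xa(params)
    lo, hi = sigma_a_range(*sigma_Y_range, motor, params)
    return dict(
        Y_star=cheYp_mean(params, motor, xi_a_star),
        xi_a_star=xi_a_star,
        sigma_a_low=lo, sigma_a_high=hi,
        delta_pcw_bound_low=delta_pcw_bound(sigma_Y_range[0], motor),
        delta_pcw_bound_high=delta_pcw_bound(sigma_Y_range[1], motor),
        sigma_Y_low=sigma_Y_range[0], sigma_Y_high=sigma_Y_range[1],
    )
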