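"""The bias-variance decision rule between additive and GxE estimation.

For a focal context A, the stratified (GxE) estimator is unbiased with

    MSE_gxe = V_A,

while the pooled (additive) estimator beta_pooled = omega_A beta_A_hat +
omega_B beta_B_hat has

    MSE_additive = ((omega_A - 1) beta_A + omega_B beta_B)^2
                   + omega_A^2 V_A + omega_B^2 V_B.

GxE estimation is preferred exactly when MSE_additive > MSE_gxe.  In the
equal-heterozygosity regime (omega_A + omega_B = 1) the rule is a
comparison of the dimensionless signal-to-noise ratio
(beta_A - beta_B)^2 / V_A against the threshold

    (1 + omega_A) / (1 - omega_A) - V_B / V_A,

which is negative — GxE always preferred — once the noise ratio
r = V_A / V_B drops below r* = (1 - omega_A) / (1 + omega_A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecisionInput",
    "Decision",
    "mse_pair",
    "snr_threshold",
    "critical_noise_ratio",
    "boundary_equal_het",
]


@dataclass(frozen=True)
class DecisionInput:
    """Parameters of the decision rule for one focal context.

    ``beta_a``/``beta_b`` may be true effects (for theory) or plug-in
    estimates (for screening); ``var_a``/``var_b`` are the stratified
    estimators' sampling variances V_A, V_B.
    """

    beta_a: float
    beta_b: float
    var_a: float
    var_b: float
    omega_a: float
    omega_b: float
    noise_ratio: float = field(init=False)

    def __post_init__(self):
        if not (self.var_a > 0 and self.var_b > 0):
            raise ValueError("sampling variances must be positive")
        if self.omega_a < 0 or self.omega_b < 0:
            raise ValueError("omega weights must be non-negative")
        object.__setattr__(self, "noise_ratio", self.var_a / self.var_b)


@dataclass(frozen=True)
class Decision:
    """Verdict of the rule: MSEs of both estimators and the preference."""

    mse_additive: float
    mse_gxe: float
    preferred: str

    @property
    def margin(self) -> float:
        """MSE_additive - MSE_gxe; positive means GxE is preferred."""
        return self.mse_additive - self.mse_gxe


def mse_pair(inp: DecisionInput) -> Decision:
    """Analytic MSEs of the additive and GxE estimators for the focal context.

    Ties (zero margin) resolve to ``"additive"`` on parsimony grounds.
    """
    bias = (inp.omega_a - 1.0) * inp.beta_a + inp.omega_b * inp.beta_b
    mse_additive = bias**2 + inp.omega_a**2 * inp.var_a + inp.omega_b**2 * inp.var_b
    mse_gxe = inp.var_a
    preferred = "gxe" if mse_additive > mse_gxe else "additive"
    return Decision(mse_additive=mse_additive, mse_gxe=mse_gxe, preferred=preferred)


def snr_threshold(omega_a: float, var_ratio_ba: float) -> float:
    """Signal-to-noise threshold for preferring GxE (equal heterozygosity).

    GxE is preferred iff (beta_a - beta_b)^2 / V_A exceeds the returned
    value, ``(1 + omega_a)/(1 - omega_a) - var_ratio_ba`` with
    ``var_ratio_ba = V_B / V_A``.  A negative return means GxE is
    preferred at every signal level.
    """
    omega_a = float(omega_a)
    if not 0.0 < omega_a < 1.0:
        raise ValueError("omega_a must lie strictly in (0, 1)")
    if var_ratio_ba <= 0:
        raise ValueError("var_ratio_ba must be positive")
    return (1.0 + omega_a) / (1.0 - omega_a) - float(var_ratio_ba)


def critical_noise_ratio(omega_a: float) -> float:
    """Critical r* = V_A/V_B below which GxE is always preferred.

    r* = (1 - omega_a) / (1 + omega_a); e.g. 1/3 at omega_a = 1/2.  For
    r = V_A/V_B < r*, focal-context estimation noise is so much smaller
    than the other context's that pooling can only hurt.
    """
    omega_a = float(omega_a)
    if not 0.0 < omega_a < 1.0:
        raise ValueError("omega_a must lie strictly in (0, 1)")
    return (1.0 - omega_a) / (1.0 + omega_a)


def boundary_equal_het(n: int, m: int, delta_beta: float) -> float:
    """Decision-boundary variance V_A at which both MSEs coincide.

    Assumes equal heterozygosity and V_A = V_B, so omega_A = n/(n+m).
    Returns (m / 2n) * delta_beta**2 on the variance scale; its square
    root is the standard-error form used on boundary plots.  At the
    returned V_A, the :func:`mse_pair` margin is zero.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be at least 1")
    return (m / (2.0 * n)) * float(delta_beta) ** 2
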