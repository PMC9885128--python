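"""Statistical power for a binary-outcome two-sample MR design.

Non-centrality approximation for the Wald test of a log odds-ratio θ using
instruments explaining a fraction r²_gx of the exposure variance, in an
outcome GWAS of n individuals with case fraction K:

    power = Φ( |θ|·sqrt(n · r²_gx · K·(1−K)) − z_{1−α/2} )

Power above 0.8 is conventionally considered adequate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

logger = logging.getLogger("mrmediate")


@dataclass
class PowerSpec:
    """Design parameters for a binary-outcome MR power calculation."""

    n_outcome: int
    case_fraction: float
    r2_gx: float
    theta: float
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_outcome <= 0:
            raise ValueError("n_outcome must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 0 <= self.r2_gx < 1:
            raise ValueError("r2_gx must lie in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PowerResult:
    power: float
    adequate: bool  # power > 0.8
    ncp: float


def mr_power_binary(spec: PowerSpec) -> PowerResult:
    """Power of the IVW Wald test under the non-centrality approximation.

    Degenerate design with r²_gx = 0 returns power = alpha (the test's
    two-sided size) with a warning.
    """
    spec.validate()
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    if spec.r2_gx == 0:
        logger.warning("mr_power_binary: r2_gx = 0, instruments explain nothing; power = alpha")
        return PowerResult(power=spec.alpha, adequate=spec.alpha > 0.8, ncp=0.0)
    k = spec.case_fraction
    ncp = abs(spec.theta) * (spec.n_outcome * spec.r2_gx * k * (1.0 - k)) ** 0.5
    power = float(stats.norm.cdf(ncp - z))
    return PowerResult(power=power, adequate=power > 0.8, ncp=float(ncp))
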