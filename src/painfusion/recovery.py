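"""Generate-and-refit protocol for the reference cluster equations.

Simulate a synthetic single-cluster cohort from one of the published
per-cluster ARX equations (with its published residual scale as the noise
SD), rebuild the design with the generating terms, and refit by Gaussian
maximum likelihood.  Used to check that the estimation machinery recovers
the printed coefficients within sampling error.
"""

from __future__ import annotations

from .arx import ARXSpec, PainARXModel, PainARXResults
from .config import CohortConfig
from .equations import CLUSTER_EQUATIONS, CLUSTER_NOISE_SD
from .synth import generate_cohort


def recover_equation(cluster: int, n_patients: int = 2000,
                     noise_sd: float | None = None,
                     seed: int = 0) -> PainARXResults:
    """Refit the reference equation of ``cluster`` on its own simulation.

    The cohort is drawn entirely from the cluster's covariate profile with
    every week observed (the dose titration ladder provides the lag
    variation that identifies the dose terms).  Returns the fitted
    :class:`PainARXResults`; compare ``params`` with
    :data:`painfusion.equations.CLUSTER_EQUATIONS` and judge agreement
    against ``bse``.
    """
    if noise_sd is None:
        noise_sd = CLUSTER_NOISE_SD[cluster]
    mix = tuple(1.0 if c == cluster else 0.0 for c in range(1, 7))
    config = CohortConfig(n_obs=n_patients, n_rct=0, seed=seed,
                          noise_sd=noise_sd, cluster_mix=mix,
                          missing_weeks_obs=frozenset())
    cohort, panel = generate_cohort(config)
    spec = ARXSpec(tuple(t for t in CLUSTER_EQUATIONS[cluster]
                         if t != "const"))
    return PainARXModel.from_panel(panel, cohort, spec,
                                   cluster_id=cluster).fit()
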