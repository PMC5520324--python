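"""Cohort-generation configuration and cluster parameter loading."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError

DEFAULT_WEEKS = (0, 1, 2, 3, 4, 5, 6)
DEFAULT_MISSING_WEEKS = frozenset({2, 4, 5})


def load_cluster_params(path=None) -> dict:
    """Load the per-cluster generator parameters.

    With no argument the versioned parameter file shipped with the package is
    used; pass a path to override with a user file of the same layout.
    """
    if path is None:
        ref = importlib.resources.files("painfusion") / "data" / "cluster_params.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    params = yaml.safe_load(text)
    mix = np.asarray(params["cluster_mix"], dtype=float)
    params["cluster_mix"] = (mix / mix.sum()).tolist()
    params["clusters"] = {int(k): v for k, v in params["clusters"].items()}
    return params


@dataclass
class CohortConfig:
    """Study-design knobs for the synthetic cohort.

    Parameters
    ----------
    n_obs, n_rct
        Number of observational-arm and RCT-arm patients.  Defaults are the
        source study sizes (3159 German observational patients, 398 North
        American RCT patients).
    cluster_mix
        Mixing probabilities over the six latent clusters; ``None`` uses the
        parameter-file mix.  Must sum to 1.
    noise_sd
        Residual SD of the weekly pain process, pain-score units.  ``None``
        uses the per-cluster defaults from the parameter file.
    seed
        Integer seed; two runs with the same config are byte-identical.
    week_grid
        Strictly increasing observation weeks (default 0..6).
    missing_weeks_obs
        Weeks masked in the observational arm before interpolation
        (default {2, 4, 5}).
    """

    n_obs: int = 3159
    n_rct: int = 398
    cluster_mix: tuple | None = None
    noise_sd: float | None = None
    seed: int = 0
    week_grid: tuple = DEFAULT_WEEKS
    missing_weeks_obs: frozenset = field(default_factory=lambda: DEFAULT_MISSING_WEEKS)
    params_path: str | None = None

    def __post_init__(self):
        if self.n_obs < 0 or self.n_rct < 0:
            raise ConfigurationError("cohort sizes must be non-negative")
        if self.cluster_mix is not None:
            mix = np.asarray(self.cluster_mix, dtype=float)
            if mix.ndim != 1 or len(mix) != 6 or (mix < 0).any():
                raise ConfigurationError("cluster_mix must be 6 non-negative weights")
            if abs(mix.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"cluster_mix must sum to 1 (got {mix.sum():.12f})")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        weeks = tuple(self.week_grid)
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ConfigurationError("week_grid must be strictly increasing")
        self.week_grid = weeks
        bad = set(self.missing_weeks_obs) - set(weeks)
        if bad:
            raise ConfigurationError(
                f"missing_weeks_obs {sorted(bad)} not in week_grid")
        self.missing_weeks_obs = frozenset(self.missing_weeks_obs)
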