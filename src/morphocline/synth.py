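"""Synthetic specimens with known ground truth.

Two generators make every downstream stage testable without real
material:

* :func:`gen_cline_matrix` draws specimen tables shaped like the real
  data — altitude-graded collection sites, latitude clumped into a few
  collection areas, ordinal characters tied to altitude through a
  latent-threshold (polyserial) model, and RGB variables linear in
  altitude — so correlation estimators can be checked against the
  generating parameters.
* :func:`gen_specimen_images` renders flat color patches at known
  positions under a controllable exposure multiplier, with a TPS
  landmark record, so color extraction can be checked for exact
  round-trip recovery.

Both are deterministic given their seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ClineParams",
    "SyntheticImageSpec",
    "gen_cline_matrix",
    "gen_specimen_images",
    "inject_missing",
]


@dataclass
class ClineParams:
    """Generating parameters for a cline-structured specimen table.

    Defaults emulate the study material: a few dozen females collected
    between sea level and ~1100 m, latitudes clumped in four areas
    (two equatorial/northern, one at ~-14.6°, one at ~-20°), ordinal
    characters whose latent liability correlates with altitude, and RGB
    channels darkening linearly with altitude.
    """

    n_specimens: int = 50
    altitude_range: tuple[float, float] = (15.0, 1150.0)
    latitude_clusters: Sequence[tuple[float, float, float]] = (
        (4.0, 0.6, 0.15),
        (-2.0, 0.8, 0.25),
        (-14.6, 0.25, 0.2),
        (-20.2, 0.2, 0.4),
    )
    rgb_slopes: tuple[float, float, float] = (-40.0, -40.0, -30.0)  # per 1000 m
    rgb_base: tuple[float, float, float] = (150.0, 110.0, 70.0)
    noise_sd: float = 8.0
    latent_rho: Sequence[float] = (0.6,)
    n_ordinal_states: Sequence[int] = (3,)
    n_rgb_points: int = 1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_specimens <= 0:
            raise ValueError("n_specimens must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        w = sum(c[2] for c in self.latitude_clusters)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("latitude cluster weights must sum to 1")
        for rho in self.latent_rho:
            if not -1 <= rho <= 1:
                raise ValueError("latent_rho must lie in [-1, 1]")
        for k in self.n_ordinal_states:
            if k < 2:
                raise ValueError("ordinal characters need >= 2 states")
        if len(self.latent_rho) != len(self.n_ordinal_states):
            raise ValueError("latent_rho and n_ordinal_states lengths differ")


def gen_cline_matrix(params: ClineParams) -> tuple[pd.DataFrame, dict]:
    """Draw a specimen table with known cline structure.

    Ordinal character ``j`` is generated by thresholding the latent
    liability ``rho_j z + sqrt(1-rho_j²) e`` (``z`` the standardized
    altitude, ``e`` standard normal) at equally spaced standard-normal
    quantile thresholds, so the population polyserial correlation with
    altitude equals ``rho_j``.  RGB channel ``c`` of each sample point
    is ``base_c + slope_c * altitude/1000 + N(0, noise_sd)``, clipped
    to [0, 255] — clipping slightly biases recovery at extreme slopes.

    Returns the table and a ground-truth dict with the generating
    values.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_specimens
    lo, hi = params.altitude_range
    altitude = rng.uniform(lo, hi, size=n)

    weights = np.array([c[2] for c in params.latitude_clusters])
    comp = rng.choice(len(weights), size=n, p=weights)
    lat = np.array(
        [rng.normal(params.latitude_clusters[c][0], params.latitude_clusters[c][1])
         for c in comp]
    )
    lat = np.clip(lat, -90, 90)

    z = (altitude - altitude.mean()) / altitude.std()
    df = pd.DataFrame(
        {
            "specimen_id": [f"SYN{i:04d}" for i in range(n)],
            "altitude_m": altitude,
            "latitude_deg": lat,
        }
    )
    thresholds = {}
    for j, (rho, k) in enumerate(zip(params.latent_rho, params.n_ordinal_states)):
        latent = rho * z + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
        # equally spaced cumulative probabilities -> standard normal thresholds
        tau = norm.ppf(np.arange(1, k) / k)
        df[f"char_{j:02d}"] = np.searchsorted(tau, latent).astype(int)
        thresholds[j] = tau
    for p in range(params.n_rgb_points):
        for c, band in enumerate("RGB"):
            mu = params.rgb_base[c] + params.rgb_slopes[c] * altitude / 1000.0
            vals = mu + rng.normal(0.0, params.noise_sd, size=n)
            df[f"p{p + 1}_{band}"] = np.clip(vals, 0, 255)
    truth = {
        "latent_rho": tuple(params.latent_rho),
        "thresholds": thresholds,
        "rgb_slopes": params.rgb_slopes,
        "rgb_base": params.rgb_base,
        "altitude_z": z,
    }
    return df, truth


@dataclass
class SyntheticImageSpec:
    """A flat-background image with uniform circular color patches."""

    width: int = 120
    height: int = 90
    background_gray: int = 230
    patches: Sequence[tuple[int, int, int, tuple[int, int, int]]] = field(
        default_factory=list
    )  # (cx, cy, radius, (R, G, B))
    exposure_multiplier: float = 1.0

    def __post_init__(self):
        if self.exposure_multiplier <= 0:
            raise ValueError("exposure multiplier must be positive")
        for cx, cy, r, rgb in self.patches:
            if not (r <= cx < self.width - r and r <= cy < self.height - r):
                raise ValueError(f"patch at ({cx}, {cy}) overhangs the frame")
            if not all(0 <= v <= 255 for v in rgb):
                raise ValueError(f"patch color out of range: {rgb}")


def gen_specimen_images(
    spec: SyntheticImageSpec, seed: int = 0
) -> tuple[np.ndarray, dict, list[tuple[int, int, int]]]:
    """Render the patch image, its TPS-style landmark record, true colors.

    The image holds each patch at its stated color multiplied by
    ``exposure_multiplier`` (clipped to [0, 255]); the landmark record
    lists patch centers in TPS convention (origin bottom-left); the
    returned colors are the pre-exposure ground truth.  Deterministic:
    the same spec and seed give a byte-identical image.
    """
    for i, (cx, cy, r, _) in enumerate(spec.patches):
        for j, (cx2, cy2, r2, _) in enumerate(spec.patches):
            if i < j and (cx - cx2) ** 2 + (cy - cy2) ** 2 <= (r + r2) ** 2:
                warnings.warn(f"patches {i} and {j} overlap", stacklevel=2)
    img = np.full(
        (spec.height, spec.width, 3), spec.background_gray, dtype=np.float64
    )
    for cx, cy, r, rgb in spec.patches:
        yy, xx = np.ogrid[:spec.height, :spec.width]
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        img[disc] = rgb
    img = np.clip(np.rint(img * spec.exposure_multiplier), 0, 255).astype(np.uint8)
    landmarks = {
        "landmarks": [(float(cx), float(spec.height - 1 - cy))
                      for cx, cy, _, _ in spec.patches],
        "image": f"synthetic_{seed}.png",
        "id": str(seed),
    }
    true_colors = [rgb for _, _, _, rgb in spec.patches]
    return img, landmarks, true_colors


def inject_missing(
    table: pd.DataFrame,
    rate: float,
    seed: int = 0,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Set a uniform random fraction of cells to missing.

    Each cell of the selected columns independently becomes missing with
    probability ``rate`` (missing-at-random).  Emulates damaged or
    absent body parts in real material.  Returns a copy.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    out = table.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    cols = list(columns) if columns is not None else list(out.columns)
    mask = rng.random((len(out), len(cols))) < rate
    for cj, col in enumerate(cols):
        hit = mask[:, cj]
        if hit.any():
            out[col] = out[col].astype(object if out[col].dtype.kind in "iu" else out[col].dtype)
            out.loc[hit, col] = None
    return out
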