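"""Geometric simulation oracles used to verify the stereological estimators.

These simulate the 3D geometry that the closed-form estimators summarize:

* sphere–slab sectioning: spheres of diameter D with centers along an axis,
  counted whenever they intersect a slab of thickness T.  The ratio of
  centers inside the slab (the unbiased count) to intersecting spheres (the
  profile count) estimates the thickness-correction factor T/(T+D).
* cylinder phantom: a virtual tissue block made of straight tubules of known
  total length, for which the length estimator must be exact.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sphere_slab_factor", "cylinder_phantom_volume_ml"]


def sphere_slab_factor(
    diameter_um: float,
    thickness_um: float,
    n_spheres: int = 500_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo estimate of the fraction of counted nuclear profiles whose
    center lies inside the section.

    Sphere centers are drawn uniformly along the sectioning axis over a
    window that covers every position from which a sphere can touch the slab
    ``[0, T]``; a sphere is a "profile" when it intersects the slab and a
    "true" count when its center falls inside.  The expectation of
    true/profiles is ``T / (T + D)``.
    """
    if thickness_um <= 0 or diameter_um < 0 or n_spheres <= 0:
        raise ValueError("need thickness > 0, diameter >= 0, n_spheres > 0")
    rng = rng or np.random.default_rng()
    half = diameter_um / 2.0
    margin = half + thickness_um  # beyond any possible contact
    centers = rng.uniform(-margin, thickness_um + margin, size=n_spheres)
    profiles = (centers > -half) & (centers < thickness_um + half)
    true = (centers >= 0) & (centers <= thickness_um)
    n_profiles = int(profiles.sum())
    if n_profiles == 0:
        raise ValueError("no profiles sampled; increase n_spheres")
    return float(true.sum() / n_profiles)


def cylinder_phantom_volume_ml(
    length_m: float, diameter_um: float, fill_fraction: float
) -> float:
    """Tissue volume (mL) of a phantom in which straight cylinders of total
    length ``length_m`` and diameter ``diameter_um`` occupy ``fill_fraction``
    of the block.  Feeding this volume, fraction and diameter to the length
    estimator must return ``length_m`` exactly."""
    if not 0 < fill_fraction <= 1:
        raise ValueError("fill_fraction must be in (0, 1]")
    if length_m <= 0 or diameter_um <= 0:
        raise ValueError("length and diameter must be > 0")
    area_um2 = np.pi * (diameter_um / 2.0) ** 2
    tubule_volume_um3 = length_m * 1e6 * area_um2
    return float(tubule_volume_um3 / fill_fraction / 1e12)
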