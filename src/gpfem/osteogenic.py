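"""Osteogenic index from principal stresses over the nine load instances.

The osteogenic index (OI) scores mechanically modulated growth per
growth-plate element:

    OI = a * max_i(sigma_S,i) + b * min_i(sigma_H,i)        [month^-1]

where sigma_S is the octahedral shear stress, sigma_H the hydrostatic
stress, and i runs over the load instances.  Shear promotes growth
(weight ``a``), hydrostatic compression inhibits it (weight ``b``); the
defaults a = 0.02, b = 0.01 MPa^-1 month^-1 give the conventional ratio
b/a = 0.5.  The OI is evaluated on the most distal plate layer outside the
stiffness transition zone, and rim outliers are replaced using a scaled-MAD
rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

N_INSTANCES = 9
#: conventional scaled-MAD factor (consistent estimator of sigma for normals)
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class OIConfig:
    a: float = 0.02  # MPa^-1 month^-1, octahedral shear weight
    b: float = 0.01  # MPa^-1 month^-1, hydrostatic weight
    evaluation_layer: int | None = None  # default: most distal non-transition
    outlier_mad_threshold: float = 3.0
    #: octahedral shear convention: sqrt(sum)/3 (standard) vs sqrt(sum/3)
    shear_sqrt_inside: bool = False

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("OI constants a and b must be positive")


def octahedral_shear(s1, s2, s3, sqrt_inside: bool = False):
    """Octahedral shear stress (1/3) sqrt((s1-s2)^2 + (s2-s3)^2 + (s3-s1)^2).

    Symmetric in its arguments; ``sqrt_inside`` switches to the alternative
    sqrt(sum/3) reading.
    """
    s1, s2, s3 = (np.asarray(s, float) for s in (s1, s2, s3))
    if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2)) and np.all(np.isfinite(s3))):
        raise ValueError("principal stresses must be finite")
    q = (s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2
    if sqrt_inside:
        return np.sqrt(q / 3.0)
    return np.sqrt(q) / 3.0


def hydrostatic(s1, s2, s3):
    """Hydrostatic (mean) stress (s1 + s2 + s3)/3; negative in compression."""
    s1, s2, s3 = (np.asarray(s, float) for s in (s1, s2, s3))
    if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2)) and np.all(np.isfinite(s3))):
        raise ValueError("principal stresses must be finite")
    return (s1 + s2 + s3) / 3.0


@dataclass
class OIField:
    element_ids: np.ndarray  # indices into the mesh's element list
    centroids: np.ndarray  # (n, 3) mm
    oi: np.ndarray  # (n,) month^-1
    flags: np.ndarray  # (n,) "raw" | "outlier_replaced"
    layer: int = 0
    meta: dict = field(default_factory=dict)


def compute_oi(stress_fields, config: OIConfig, mesh, material_set=None) -> OIField:
    """Per-element OI on the evaluation layer of the growth plate.

    ``stress_fields`` is one StressField (or (E,3) principal array) per
    load instance; all instances must be present.
    """
    principals = []
    for sf in stress_fields:
        p = sf.principal if hasattr(sf, "principal") else np.asarray(sf, float)
        principals.append(p)
    shapes = {p.shape for p in principals}
    if len(shapes) != 1:
        raise ValueError("stress fields have inconsistent element counts")
    P = np.stack(principals)  # (n_inst, E, 3)
    if not np.all(np.isfinite(P)):
        bad = np.where(~np.isfinite(P).all(axis=(0, 2)))[0]
        raise ValueError(f"non-finite stresses for elements {bad[:5]}...")

    layer = config.evaluation_layer
    if layer is None:
        from gpfem.fe import MATERIAL_SETS, evaluation_layer_default

        layer = evaluation_layer_default(material_set or MATERIAL_SETS["hard"])
    ids = np.where(mesh.gp_layer == layer)[0]
    if ids.size == 0:
        raise ValueError(f"no elements on growth-plate layer {layer}")

    s = P[:, ids, :]
    sigma_s = octahedral_shear(
        s[..., 0], s[..., 1], s[..., 2], sqrt_inside=config.shear_sqrt_inside
    )
    sigma_h = hydrostatic(s[..., 0], s[..., 1], s[..., 2])
    oi = config.a * sigma_s.max(axis=0) + config.b * sigma_h.min(axis=0)
    oi_clean, flags = replace_outliers(oi, config.outlier_mad_threshold)
    return OIField(
        element_ids=ids,
        centroids=mesh.centroids(ids),
        oi=oi_clean,
        flags=flags,
        layer=int(layer),
        meta=dict(a=config.a, b=config.b, raw_oi=oi),
    )


def replace_outliers(values, threshold: float = 3.0):
    """Scaled-MAD outlier replacement.

    Values more than ``threshold`` scaled MADs (1.4826 * median absolute
    deviation) from the median are replaced by the maximum (high outliers)
    or minimum (low outliers) non-outlier value.  Returns the cleaned copy
    and per-value flags; idempotent.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("need at least 3 values for outlier detection")
    med = np.median(x)
    smad = MAD_SCALE * np.median(np.abs(x - med))
    flags = np.full(x.size, "raw", dtype=object)
    if smad == 0:
        if np.any(x != med):
            warnings.warn(
                "scaled MAD is zero with non-constant data; skipping replacement",
                stacklevel=2,
            )
        return x.copy(), flags.astype(str)
    out_hi = x - med > threshold * smad
    out_lo = med - x > threshold * smad
    ok = ~(out_hi | out_lo)
    cleaned = x.copy()
    if out_hi.any():
        cleaned[out_hi] = x[ok].max()
        flags[out_hi] = "outlier_replaced"
    if out_lo.any():
        cleaned[out_lo] = x[ok].min()
        flags[out_lo] = "outlier_replaced"
    return cleaned, flags.astype(str)
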