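"""Shared fixtures: phantoms and digital-cylinder volumes are generated at
test time, never stored."""

from __future__ import annotations

import numpy as np
import pytest

import qctlung as q
from qctlung.core import CTVolume


@pytest.fixture(scope="session")
def hf_phantom():
    """A default-size heart-failure-like phantom (25% EVLW weight)."""
    spec = q.PhantomSpec(evlw_weight=0.25, seed=3)
    vol, truth = q.build_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def control_phantom():
    """A default-size control-like phantom (5% EVLW weight)."""
    spec = q.PhantomSpec(evlw_weight=0.05, seed=3)
    vol, truth = q.build_phantom(spec)
    return spec, vol, truth


def compact_spec(**kwargs) -> q.PhantomSpec:
    """A smaller, faster phantom spec that still fits 6 generations."""
    defaults = dict(grid_shape=(96, 88, 88), root_length=24.0,
                    length_ratio=0.72)
    defaults.update(kwargs)
    return q.PhantomSpec(**defaults)


def write_rendered_cohort(tmp_path, n_per_group: int = 2):
    """Render a small two-group phantom cohort to NIfTI files and write a
    manifest CSV; returns the manifest path."""
    import pandas as pd

    from qctlung import io

    rows = []
    rng = np.random.default_rng(0)
    i = 0
    for group, w in [("control", 0.05), ("hf", 0.25)]:
        for _ in range(n_per_group):
            spec = compact_spec(evlw_weight=w, seed=100 + i)
            vol, truth = q.build_phantom(spec)
            post, _ = q.apply_bronchodilator(vol, truth, 0.9, 0.12, seed=200 + i)
            pre_p = tmp_path / f"s{i}_pre.nii.gz"
            post_p = tmp_path / f"s{i}_post.nii.gz"
            io.write_volume(vol, pre_p)
            io.write_volume(post, post_p)
            rows.append({
                "subject_id": f"s{i}", "group": group,
                "tlc": float(rng.normal(6.0, 0.5)),
                "fvc_pct": float(rng.normal(100, 10)),
                "fev1_pct": float(rng.normal(100, 10)),
                "fef2575_pct": float(rng.normal(100, 20)),
                "pef_pct": float(rng.normal(100, 15)),
                "pre_path": str(pre_p), "post_path": str(post_p),
            })
            i += 1
    manifest = tmp_path / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def make_cylinder(radius: float, wall: float, spacing: float,
                  oblique: bool = False, length: float = 40.0,
                  background_hu: float = -897.0):
    """Digital cylinder (lumen -1000 HU, wall +30 HU) with its analytic
    centerline; axis-aligned or at 45 degrees to the grid."""
    pad = 12.0
    if oblique:
        ext = np.array([length * 0.75 + 2 * pad, 2 * (radius + wall + pad),
                        length * 0.75 + 2 * pad])
        d = np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0)
        p0 = np.array([pad, ext[1] / 2, pad])
    else:
        ext = np.array([length, 2 * (radius + wall + pad),
                        2 * (radius + wall + pad)])
        d = np.array([1.0, 0.0, 0.0])
        p0 = np.array([0.0, ext[1] / 2, ext[2] / 2])
    shape = np.ceil(ext / spacing).astype(int)
    zz, yy, xx = np.meshgrid(
        *[(np.arange(s) + 0.5) * spacing for s in shape], indexing="ij")
    pts = np.stack([zz, yy, xx], -1)
    t = np.tensordot(pts - p0, d, axes=([-1], [0]))
    dist = np.linalg.norm(pts - p0 - t[..., None] * d, axis=-1)
    vals = np.full(tuple(shape), background_hu)
    vals[dist < radius + wall] = 30.0
    vals[dist < radius] = -1000.0
    vol = CTVolume(vals, spacing=(spacing,) * 3)
    s_arr = np.linspace(5.0, length - 5.0, 30)
    centerline = p0[None, :] + s_arr[:, None] * d[None, :]
    return vol, centerline
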