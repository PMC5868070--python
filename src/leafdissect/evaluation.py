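"""Self-contained evaluation harness: oracle checks and synthetic-grid
recovery metrics.

Everything here recomputes its quantity from scratch by running the
package on generated inputs: brute-force oracles for the cut-point
minimization and the distance transform, leaflet-count/length recovery
over the synthetic parameter grid, landmark contracts, and the
population-level checks.  Both the test-suite and the reproduction
script build on these functions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import skeleton as sk
from .binarize import binarize
from .dissect import cut_index_on_path
from .features import FeatureTable
from .landmarks import outline_trace, place_landmarks, terminal_top_point
from .pipeline import analyze_mask
from .population import build_metaleaf, merged_feature_pca
from .synthetic import generate_leaf, random_grid_spec

__all__ = [
    "cut_point_oracle_agreement",
    "distance_transform_exact_match",
    "GridRecovery",
    "grid_recovery",
    "eccentricity_checks",
    "landmark_checks",
    "population_checks",
]


def _brute_force_cut(labels) -> tuple[int, int]:
    """Direct evaluation of the misclassification count at every split."""
    is_l = np.asarray([x == "L" for x in labels])
    is_r = ~is_l
    n = len(labels)
    best_k, best_m = 0, None
    for k in range(n + 1):
        m = int(is_l[:k].sum()) + int(is_r[k:].sum())
        if best_m is None or m < best_m:
            best_k, best_m = k, m
    return best_k, best_m


def cut_point_oracle_agreement(
    seed: int, n_sequences: int = 10_000, max_len: int = 200
) -> float:
    """Fraction of random label sequences on which the cut-point search
    agrees exactly (index and value) with the brute-force scan."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_sequences):
        n = int(rng.integers(1, max_len + 1))
        p = rng.uniform(0.1, 0.9)
        labels = np.where(rng.random(n) < p, "L", "R").tolist()
        if cut_index_on_path(labels) == _brute_force_cut(labels):
            agree += 1
    return agree / n_sequences


def _brute_force_edt(mask: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import cdist

    padded = np.pad(mask, 1, constant_values=False)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    out = np.zeros(padded.shape)
    if len(fg):
        out[tuple(fg.T)] = cdist(fg, bg).min(axis=1)
    return out[1:-1, 1:-1]


def distance_transform_exact_match(
    seed: int, n_masks: int = 100, size: int = 50
) -> float:
    """Fraction of random masks whose distance transform matches the
    all-pairs brute-force minimum exactly (to 1e-9)."""
    rng = np.random.default_rng(seed)
    match = 0
    for _ in range(n_masks):
        density = rng.uniform(0.2, 0.8)
        mask = rng.random((size, size)) < density
        if not mask.any():
            mask[size // 2, size // 2] = True
        d = sk.distance_transform(mask)
        if np.allclose(d, _brute_force_edt(mask), atol=1e-9):
            match += 1
    return match / n_masks


@dataclass
class GridRecovery:
    """Recovery metrics over the synthetic evaluation grid."""

    n_leaves: int
    count_accuracy: float  # fraction of leaves with exact leaflet count
    jaccard_median: float
    petiolule_rel_dev_median: float
    rachis_rel_dev_median: float
    failures: list[str] = field(default_factory=list)


def grid_recovery(seed: int, n_leaves: int = 50, from_image: bool = True) -> GridRecovery:
    """Run the full pipeline over ``n_leaves`` random grid leaves
    (1-7 lateral pairs, semi-major axes 8-40 px, stem widths 2-6 px)
    and score leaflet-count, mask and length recovery against the
    generator's ground truth."""
    rng = np.random.default_rng(seed)
    n_correct = 0
    jaccards: list[float] = []
    pet_devs: list[float] = []
    rachis_devs: list[float] = []
    failures: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_leaves):
            spec = random_grid_spec(rng)
            truth = generate_leaf(spec)
            try:
                mask = binarize(truth.image) if from_image else truth.mask
                res = analyze_mask(mask, leaf_id=f"grid{i}")
            except Exception as exc:  # count as a miss, never abort
                failures.append(f"leaf {i}: {type(exc).__name__}: {exc}")
                continue
            if res.n_leaflets == truth.n_leaflets:
                n_correct += 1
            for j in range(len(res.cuts.leaflets)):
                det = res.dissection.leaflet_mask(j)
                if det.any():
                    jaccards.append(
                        max(
                            np.logical_and(det, tm).sum()
                            / np.logical_or(det, tm).sum()
                            for tm in truth.leaflet_masks
                        )
                    )
            true_rachis = truth.unit_lengths["rachis"]
            rachis_devs.append(
                abs(res.features.rachis_length - true_rachis) / true_rachis
            )
            true_pet = truth.unit_lengths.get("petiolule_0")
            if true_pet:
                for fl in res.features.leaflets:
                    if fl.side in ("left", "right") and np.isfinite(fl.petiolule_length):
                        pet_devs.append(abs(fl.petiolule_length - true_pet) / true_pet)
    return GridRecovery(
        n_leaves=n_leaves,
        count_accuracy=n_correct / n_leaves,
        jaccard_median=float(np.median(jaccards)) if jaccards else 0.0,
        petiolule_rel_dev_median=float(np.median(pet_devs)) if pet_devs else math.inf,
        rachis_rel_dev_median=float(np.median(rachis_devs)) if rachis_devs else math.inf,
        failures=failures,
    )


def eccentricity_checks() -> dict[str, float]:
    """Analytic shape checks: a rasterized disk is near-circular and a
    2:1 ellipse has eccentricity close to sqrt(3)/2."""
    from skimage.draw import disk as draw_disk
    from skimage.draw import ellipse as draw_ellipse

    from .features import leaflet_shape_features

    disk_mask = np.zeros((60, 60), dtype=bool)
    rr, cc = draw_disk((30, 30), 20)
    disk_mask[rr, cc] = True
    circle_e = leaflet_shape_features(disk_mask).eccentricity

    ell_mask = np.zeros((90, 140), dtype=bool)
    rr, cc = draw_ellipse(45, 70, 30, 60)
    ell_mask[rr, cc] = True
    ell_e = leaflet_shape_features(ell_mask).eccentricity
    return {
        "circle_eccentricity": circle_e,
        "ellipse_eccentricity_abs_err": abs(ell_e - math.sqrt(3) / 2),
    }


def landmark_checks() -> dict[str, float]:
    """Landmark contract on a rotated test ellipse: exactly 8 on-outline
    points, equivariant under 90/180/270-degree rotations."""
    from skimage.draw import ellipse as draw_ellipse

    mask = np.zeros((120, 100), dtype=bool)
    rr, cc = draw_ellipse(60, 50, 40, 22, rotation=0.3)
    mask[rr, cc] = True
    base, cut = (115.0, 50.0), (99.0, 48.0)

    def landmarks_for(m, b, c):
        tr = outline_trace(m)
        top = terminal_top_point(tr, b, c)
        return place_landmarks(tr, b, top).points, tr

    pts0, tr0 = landmarks_for(mask, base, cut)

    def rot_pt(p, k, shape):
        r, c = p
        h, w = shape
        for _ in range(k):
            r, c = w - 1 - c, r
            h, w = w, h
        return (r, c)

    max_err = 0.0
    for k in (1, 2, 3):
        m_r = np.rot90(mask, k=k)
        b_r = rot_pt(base, k, mask.shape)
        c_r = rot_pt(cut, k, mask.shape)
        pts_r, _ = landmarks_for(m_r, b_r, c_r)
        for p in pts0:
            target = np.asarray(rot_pt(tuple(p), k, mask.shape))
            max_err = max(max_err, float(np.hypot(*(pts_r - target).T).min()))

    # on-outline membership of the unrotated set
    chain = tr0.points
    def dist_chain(p):
        best = np.inf
        for a, b2 in zip(chain[:-1], chain[1:]):
            ab = b2 - a
            t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-12), 0, 1)
            best = min(best, float(np.hypot(*(a + t * ab - p))))
        return best

    on_outline_max = max(dist_chain(np.asarray(p)) for p in pts0)
    return {
        "landmark_count": float(len(pts0)),
        "rotation_equivariance_max_err_px": max_err,
        "on_outline_max_dist_px": on_outline_max,
    }


def population_checks(seed: int, n_per_group: int = 5) -> dict[str, float]:
    """Normalization exactness, PCA variance ordering, and group
    separation (silhouette on PC1-PC2) for two synthetic groups with
    well-separated size parameters."""
    import pandas as pd
    from sklearn.metrics import silhouette_score

    from .synthetic import SyntheticLeafSpec

    tables = []
    groups: dict[str, str] = {}
    norm_residual = 0.0
    markers = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gi, size in enumerate((18.0, 30.0)):
            table = FeatureTable()
            for i in range(n_per_group):
                spec = SyntheticLeafSpec(
                    n_lateral_pairs=3,
                    leaflet_semi_axes=(size, 0.6 * size),
                    terminal_leaflet_semi_axes=(1.2 * size, 0.72 * size),
                    petiolule_lengths=26.0 + (size - 20.0),
                    petiole_length=55.0 + 2 * (i % 4),
                    seed=seed + 100 * gi + i,
                )
                leaf_id = f"g{gi}_{i}"
                res = analyze_mask(generate_leaf(spec).mask, leaf_id=leaf_id)
                table.append(res.features)
                groups[leaf_id] = "A" if gi == 0 else "B"
                if res.markers is not None:
                    markers.append(res.markers)
                    norm_residual = max(
                        norm_residual,
                        float(np.abs(res.markers["base"]).max()),
                        float(np.abs(res.markers["top"] - [[0, 1]]).max()),
                    )
            tables.append(table.to_frame())

    build_metaleaf(markers)  # must pool without error
    df = pd.concat(tables, ignore_index=True)
    res = merged_feature_pca(df)
    ev = res.explained_variance
    labels = [groups[i] for i in res.scores.index]
    sil = float(silhouette_score(res.scores[["PC1", "PC2"]].values, labels))
    return {
        "normalization_max_residual": norm_residual,
        "explained_variance_monotone": float(np.all(np.diff(ev) <= 1e-9)),
        "pc12_group_silhouette": sil,
    }
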