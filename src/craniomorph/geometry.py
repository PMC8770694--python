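"""Superimposition and shape-derived scalar traits.

Generalized Procrustes Analysis (GPA) here is full Procrustes: translate to
the centroid, scale to unit centroid size, and rotate (rotation only,
det = +1) to an iteratively updated consensus. Aligned coordinates are
treated as Euclidean tangent-space coordinates downstream; no separate
orthogonal projection is applied, which is adequate while shape variation
is small relative to the consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator

from .io import LandmarkConfiguration

#: 1-based indices deleted to obtain the one-sided (midline + right) subset.
LEFT_SIDE_LANDMARKS = tuple(range(23, 45))

#: 1-based landmark numbers used by the facial length index:
#: orbit -> anterior premaxilla over orbit -> posterior ventral cranium.
FACIAL_LENGTH_LANDMARKS = (5, 13, 52)


class MissingLandmarkError(ValueError):
    """Operation requires complete configurations."""


@dataclass
class ProcrustesAlignment:
    """GPA result: dimensionless shape coordinates plus size information."""

    aligned: np.ndarray          # (n, k, 3)
    centroid_size: np.ndarray    # (n,), mm
    consensus: np.ndarray        # (k, 3), unit centroid size
    iterations: int
    converged: bool
    specimen_ids: list[str]
    species: list[str]
    landmark_labels: list[str]
    ss_history: list[float] = None  # total residual SS per iteration, non-increasing

    @property
    def log_centroid_size(self) -> np.ndarray:
        """The study's "size" variable."""
        return np.log(self.centroid_size)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to (n, 3k)."""
        return self.aligned.reshape(self.n_specimens, -1)

    def species_matrix(self) -> "tuple[np.ndarray, list[str]]":
        """(n, 3k) matrix and species list; requires one specimen per species."""
        if len(set(self.species)) != len(self.species):
            raise ValueError("one specimen per species required; subset first")
        return self.flat(), list(self.species)


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Root of summed squared distances of landmarks from their centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if isinstance(config, LandmarkConfiguration) and not config.is_complete:
        raise MissingLandmarkError(
            f"{config.specimen_id}: centroid size undefined with missing landmarks"
        )
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs == 0.0:
        warnings.warn("degenerate configuration: all landmarks coincide", stacklevel=2)
    return cs


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det=+1) minimizing ||source @ R - target||_F."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return u @ vt


def gpa(
    configs,
    tol: float = 1e-24,
    max_iter: int = 200,
) -> ProcrustesAlignment:
    """Generalized Procrustes Analysis of complete landmark configurations.

    ``tol`` is the squared consensus displacement between iterations at
    which iteration stops; the default is tight enough that alignments are
    reproducible to well below 1e-8 under arbitrary similarity transforms
    of the inputs.
    """
    if isinstance(configs, np.ndarray):
        X = np.asarray(configs, float)
        ids = [f"specimen{i + 1}" for i in range(X.shape[0])]
        species = list(ids)
        labels = [f"lm{str(i).zfill(2)}" for i in range(1, X.shape[1] + 1)]
    else:
        configs = list(configs)
        if any(not c.is_complete for c in configs):
            bad = [c.specimen_id for c in configs if not c.is_complete]
            raise MissingLandmarkError(
                f"estimate missing landmarks before GPA: {', '.join(bad)}"
            )
        ks = {c.n_landmarks for c in configs}
        if len(ks) > 1:
            raise ValueError(f"landmark counts differ: {sorted(ks)}")
        X = np.stack([c.coords for c in configs])
        ids = [c.specimen_id for c in configs]
        species = [c.species for c in configs]
        labels = list(configs[0].landmark_labels)
    n = X.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")

    cs = np.array([centroid_size(x) for x in X])
    if np.any(cs == 0):
        raise ValueError("degenerate configuration with zero centroid size")
    Xc = (X - X.mean(axis=1, keepdims=True)) / cs[:, None, None]

    consensus = Xc[0].copy()
    aligned = Xc.copy()
    converged = False
    iterations = 0
    ss_history: list[float] = []
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = Xc[i] @ _optimal_rotation(Xc[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus ** 2).sum())
        ss_history.append(float(((aligned - aligned.mean(axis=0)) ** 2).sum()))
        delta = float(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last delta {delta:.3e})",
            stacklevel=2,
        )
    # final rotation pass against the converged consensus
    for i in range(n):
        aligned[i] = Xc[i] @ _optimal_rotation(Xc[i], consensus)
    return ProcrustesAlignment(
        aligned=aligned, centroid_size=cs, consensus=aligned.mean(axis=0),
        iterations=iterations, converged=converged,
        specimen_ids=ids, species=species, landmark_labels=labels,
        ss_history=ss_history,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the coordinate difference of two aligned shapes."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def distance_matrix(alignment: ProcrustesAlignment) -> np.ndarray:
    """Pairwise Procrustes (shape-space Euclidean) distances."""
    flat = alignment.flat()
    diff = flat[:, None, :] - flat[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def estimate_missing_tps(
    target: LandmarkConfiguration,
    references,
) -> LandmarkConfiguration:
    """Estimate missing landmarks with a 3D thin-plate-spline interpolant.

    A TPS map is fit from the reference configuration's positions at the
    target's observed landmarks to the target's observed positions, then
    evaluated at the reference positions of the missing landmarks. The
    interpolant carries a degree-1 polynomial tail, so an affine relation
    between reference and target is recovered exactly.

    ``references``: complete configurations (ideally conspecifics); if more
    than one, they are GPA-aligned and their consensus (rescaled to the
    mean reference centroid size) is the reference form.
    """
    if target.is_complete:
        return target
    refs = [r for r in references if r.is_complete]
    if not refs:
        raise ValueError("need at least one complete reference configuration")
    if any(r.n_landmarks != target.n_landmarks for r in refs):
        raise ValueError("reference landmark count differs from target")
    if len(refs) == 1:
        ref_coords = refs[0].coords.copy()
    else:
        ali = gpa(refs)
        ref_coords = ali.consensus * ali.centroid_size.mean()

    observed = ~target.missing_mask
    anchors_ref = ref_coords[observed]
    anchors_tgt = target.coords[observed]
    if anchors_ref.shape[0] < 4:
        raise ValueError(
            f"{target.specimen_id}: need >= 4 observed landmarks to anchor the spline, "
            f"have {anchors_ref.shape[0]}"
        )
    centered = anchors_ref - anchors_ref.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= 1e-8 * s[0]:
        raise ValueError(f"{target.specimen_id}: anchor landmarks are coplanar; TPS system singular")
    interp = RBFInterpolator(anchors_ref, anchors_tgt, kernel="thin_plate_spline", degree=1)
    coords = target.coords.copy()
    coords[target.missing_mask] = interp(ref_coords[target.missing_mask])
    estimated = [int(i) + 1 for i in np.flatnonzero(target.missing_mask)]
    return LandmarkConfiguration(
        specimen_id=target.specimen_id, species=target.species, coords=coords,
        landmark_labels=list(target.landmark_labels),
        missing_mask=np.zeros(target.n_landmarks, bool),
        sex=target.sex, scan_type=target.scan_type,
        estimated_landmarks=sorted(set(target.estimated_landmarks) | set(estimated)),
    )


def symmetric_subset(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Midline plus right-side landmarks only (drop 1-based landmarks 23-44).

    Reduces covariation between mirrored bilateral landmarks ahead of
    modularity analyses; 53 landmarks become 31, order preserved.
    """
    if config.n_landmarks != 53:
        raise ValueError(f"symmetric subset is defined for k=53, got k={config.n_landmarks}")
    keep = [i for i in range(53) if (i + 1) not in LEFT_SIDE_LANDMARKS]
    return LandmarkConfiguration(
        specimen_id=config.specimen_id, species=config.species,
        coords=config.coords[keep],
        landmark_labels=[config.landmark_labels[i] for i in keep],
        missing_mask=config.missing_mask[keep],
        sex=config.sex, scan_type=config.scan_type,
        estimated_landmarks=[e for e in config.estimated_landmarks if e not in LEFT_SIDE_LANDMARKS],
    )


def symmetric_subset_alignment(alignment: ProcrustesAlignment) -> ProcrustesAlignment:
    """Apply the one-sided landmark subset to an existing alignment.

    Coordinates are subset without re-superimposition so the shape space
    stays that of the full-cranium GPA.
    """
    if alignment.n_landmarks != 53:
        raise ValueError("symmetric subset is defined for k=53")
    keep = [i for i in range(53) if (i + 1) not in LEFT_SIDE_LANDMARKS]
    return ProcrustesAlignment(
        aligned=alignment.aligned[:, keep, :],
        centroid_size=alignment.centroid_size,
        consensus=alignment.consensus[keep],
        iterations=alignment.iterations, converged=alignment.converged,
        specimen_ids=list(alignment.specimen_ids), species=list(alignment.species),
        landmark_labels=[alignment.landmark_labels[i] for i in keep],
    )


def facial_length(config: LandmarkConfiguration) -> float:
    """Facial length index on raw (untransformed) coordinates.

    Distance orbit-premaxilla over distance orbit-posterior ventral cranium
    (interlandmark distances 5-13 and 5-52); scale-invariant by construction.
    """
    lm5, lm13, lm52 = FACIAL_LENGTH_LANDMARKS
    for num in FACIAL_LENGTH_LANDMARKS:
        if config.missing_mask[num - 1]:
            raise MissingLandmarkError(
                f"{config.specimen_id}: landmark {num} required for facial length is missing"
            )
    face = np.linalg.norm(config.landmark(lm5) - config.landmark(lm13))
    cranium = np.linalg.norm(config.landmark(lm5) - config.landmark(lm52))
    if cranium == 0:
        raise ValueError("degenerate configuration: zero ventral cranial length")
    return float(face / cranium)
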