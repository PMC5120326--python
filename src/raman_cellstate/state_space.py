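"""Frozen two-class state space and time-course projection.

Supervisor data (e.g. naive and fully activated T cells) define a PC
space and a Fisher discriminant axis once; spectra measured at later
timepoints are then projected into that frozen space — PC scores by inner
product with the stored loadings, LDA scores by projection onto the F1
axis — without any refitting.  Tracking the mean LDA score across
activation stages yields the trajectory of a population through the
naive→activated state space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .core import SpectraDataset, ValidationError, WavenumberAxis, load_arrays, save_arrays
from .dapc import DiscriminantModel, fit_discriminant, lda_score, qda_log_prob
from .nipals import PCAModel, fit_nipals, project

__all__ = [
    "StateSpaceBundle",
    "TrajectoryTable",
    "build_state_space",
    "project_to_state_space",
    "timecourse_trajectory",
    "save_bundle",
    "load_bundle",
]


@dataclass
class TrajectoryTable:
    """Per-timepoint LDA scores with summary statistics.

    ``sd`` is the sample standard deviation (ddof=1), reported as 0 by
    convention when n == 1 so tables stay total.
    """

    timepoint: float
    scores: np.ndarray
    mean: float
    sd: float
    n: int


@dataclass
class StateSpaceBundle:
    """Frozen PCA + discriminant state space with preprocessing provenance.

    ``axis`` records the (cropped) wavenumber axis the supervisor spectra
    lived on; projected data must share it exactly.  ``log_prob_clip``
    holds per-class (lo, hi) log-probability ranges — the 1st and 99th
    percentiles of each class's log-probability over all supervisor cells
    — used as the default linear color scale by the colorizer.
    """

    pca: PCAModel
    disc: DiscriminantModel
    class_names: Tuple[str, str]
    axis: WavenumberAxis
    preprocess_config: dict = field(default_factory=dict)
    log_prob_clip: Optional[np.ndarray] = None  # (2, 2): per class (lo, hi)


def build_state_space(
    supervisor: SpectraDataset,
    k: int = 7,
    class_order: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    reg_eps: float = 1e-3,
    crop: Optional[Tuple[float, float]] = None,
) -> StateSpaceBundle:
    """Fit NIPALS PCA then the Fisher discriminant on supervisor data.

    The supervisor dataset must contain exactly two classes.  The returned
    bundle is treated as immutable: projecting data through it never
    refits anything.
    """
    names = supervisor.class_names()
    if len(names) != 2:
        raise ValidationError(f"supervisor data must have exactly 2 classes, found {names}")
    pca = fit_nipals(supervisor.X, k=k, tol=tol, max_iter=max_iter)
    disc = fit_discriminant(
        pca.scores_train, supervisor.labels, class_order=class_order, reg_eps=reg_eps
    )
    lp = qda_log_prob(disc, pca.scores_train)  # (n, 2)
    clip = np.stack(
        [np.percentile(lp[:, i], [1.0, 99.0]) for i in range(2)]
    )
    cfg = {"snv": True, "k": int(k), "tol": float(tol), "reg_eps": float(reg_eps)}
    if crop is None:
        # half-open bounds recovering exactly the supervisor's (cropped) axis
        v = supervisor.axis.values
        crop = (float(v[0]), float(v[-1]) + 0.5 * float(np.median(np.diff(v))))
    cfg["crop_cm1"] = (float(crop[0]), float(crop[1]))
    return StateSpaceBundle(
        pca=pca,
        disc=disc,
        class_names=disc.class_names,
        axis=supervisor.axis,
        preprocess_config=cfg,
        log_prob_clip=clip,
    )


def _as_matrix(bundle: StateSpaceBundle, data: Union[SpectraDataset, np.ndarray]) -> np.ndarray:
    if isinstance(data, SpectraDataset):
        if data.axis != bundle.axis:
            raise ValidationError(
                "dataset axis does not match the state-space axis "
                f"(bundle covers {bundle.axis.values[0]:g}-{bundle.axis.values[-1]:g} cm^-1, "
                f"{len(bundle.axis)} bands)"
            )
        return data.X
    X = np.asarray(data, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(bundle.axis):
        raise ValidationError(
            f"spectra have {X.shape[1]} bands but the state space expects {len(bundle.axis)}"
        )
    return X


def project_to_state_space(
    bundle: StateSpaceBundle, data: Union[SpectraDataset, np.ndarray]
) -> np.ndarray:
    """LDA scores of (already standardized) spectra in the frozen space.

    Equivalent to ``lda_score(disc, project(pca, X))``; never mutates the
    bundle.
    """
    X = _as_matrix(bundle, data)
    return np.atleast_1d(lda_score(bundle.disc, project(bundle.pca, X)))


def timecourse_trajectory(
    bundle: StateSpaceBundle,
    staged: Mapping[float, Union[SpectraDataset, np.ndarray]],
) -> List[TrajectoryTable]:
    """Project each stage into the frozen space; tables sorted by timepoint."""
    if not staged:
        raise ValidationError("need at least one timepoint")
    tables: List[TrajectoryTable] = []
    for t in sorted(float(t) for t in staged):
        data = staged[t] if t in staged else staged[int(t) if float(t).is_integer() else t]
        X = _as_matrix(bundle, data)
        if X.shape[0] == 0:
            raise ValidationError(f"timepoint {t} h has an empty dataset")
        s = project_to_state_space(bundle, X)
        n = s.shape[0]
        sd = float(np.std(s, ddof=1)) if n > 1 else 0.0
        tables.append(
            TrajectoryTable(timepoint=t, scores=s, mean=float(s.mean()), sd=sd, n=n)
        )
    return tables


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_bundle(path, bundle: StateSpaceBundle) -> None:
    """Serialize a bundle to the NPZ+JSON model container."""
    meta = {
        "kind": "state_space_bundle",
        "class_names": list(bundle.class_names),
        "threshold": float(bundle.disc.threshold),
        "reg_eps": float(bundle.disc.reg_eps),
        "preprocess_config": bundle.preprocess_config,
    }
    arrays = {
        "loadings": bundle.pca.loadings,
        "col_mean": bundle.pca.col_mean,
        "explained_var": bundle.pca.explained_var,
        "f1": bundle.disc.f1,
        "means": bundle.disc.means,
        "covs": bundle.disc.covs,
        "priors": bundle.disc.priors,
        "axis": bundle.axis.values,
    }
    if bundle.log_prob_clip is not None:
        arrays["log_prob_clip"] = bundle.log_prob_clip
    save_arrays(path, meta, arrays)


def load_bundle(path) -> StateSpaceBundle:
    meta, arr = load_arrays(path)
    if meta.get("kind") != "state_space_bundle":
        raise ValidationError(f"{path}: not a state-space bundle")
    pca = PCAModel(
        loadings=arr["loadings"],
        col_mean=arr["col_mean"],
        explained_var=arr["explained_var"],
    )
    names = tuple(meta["class_names"])
    disc = DiscriminantModel(
        class_names=names,
        f1=arr["f1"],
        threshold=float(meta["threshold"]),
        means=arr["means"],
        covs=arr["covs"],
        priors=arr["priors"],
        reg_eps=float(meta["reg_eps"]),
    )
    return StateSpaceBundle(
        pca=pca,
        disc=disc,
        class_names=names,
        axis=WavenumberAxis(arr["axis"]),
        preprocess_config=dict(meta.get("preprocess_config", {})),
        log_prob_clip=arr.get("log_prob_clip"),
    )
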