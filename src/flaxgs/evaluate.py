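"""Predictive-ability evaluation: within-population cross-validation,
across-population prediction (APP), and the marker-density subsampling study.

Predictive ability (PA) is the Pearson correlation between GEBVs and observed
line values.  Cross-validation uses k folds repeated over independent random
partitions (default 5 x 10 = 50 replicate evaluations); any feature
construction that depends on the samples (PC fitting, centering) must be
refit inside each training fold, which the ``featurizer`` hook makes
explicit.  APP fits on one full population and evaluates on an independent
one whose markers were harmonized beforehand.  The subsampling study draws
random SNP subsets of increasing size and maps PA against marker density,
reporting the plateau bin (smallest bin reaching 99% of the best bin mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markerio import GenotypeMatrix, harmonize
from .markerrep import MarkerSet, snp_markers
from .predict import make_model

class EvaluationError(ValueError):
    pass


def predictive_ability(gebv, observed) -> float:
    """Pearson r between predicted and observed values (raw scale)."""
    g = np.asarray(gebv, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if g.shape != o.shape or g.size < 3:
        raise EvaluationError("need >= 3 paired values")
    if np.std(g) == 0 or np.std(o) == 0:
        raise EvaluationError("correlation undefined for a constant vector")
    return float(np.corrcoef(g, o)[0, 1])


@dataclass
class CVScheme:
    k: int
    n_partitions: int
    seed: int
    folds: np.ndarray  # (n_partitions, n) fold index per sample

    @property
    def n_evaluations(self) -> int:
        return self.k * self.n_partitions


def make_cv_scheme(
    n: int, k: int = 5, partitions: int = 10, seed: int = 0
) -> CVScheme:
    """Seeded fold assignments; fold sizes differ by at most one."""
    if n < k:
        raise EvaluationError(f"n={n} smaller than k={k}")
    rng = np.random.default_rng(seed)
    folds = np.empty((partitions, n), dtype=int)
    base = np.arange(n) % k
    for p in range(partitions):
        folds[p] = base[rng.permutation(n)]
    return CVScheme(k=k, n_partitions=partitions, seed=seed, folds=folds)


@dataclass
class EvaluationResult:
    replicate_pa: np.ndarray
    mean_pa: float
    sd_pa: float
    provenance: dict = field(default_factory=dict)


def run_cv(
    markers,
    phenos,
    model_spec,
    scheme: CVScheme,
    featurizer=None,
) -> EvaluationResult:
    """Replicate PAs over all (partition, fold) pairs.

    ``markers`` is a MarkerSet/array (rows subset per fold), or, when
    ``featurizer`` is given, any object the featurizer turns into
    (train_features, test_features) from train/test row indices — that is how
    fold-refit feature construction (e.g. PCA) stays leak-free.
    """
    y = np.asarray(phenos, dtype=float).ravel()
    n = len(y)
    pas, skipped = [], 0
    for p in range(scheme.n_partitions):
        for f in range(scheme.k):
            te = np.flatnonzero(scheme.folds[p] == f)
            tr = np.flatnonzero(scheme.folds[p] != f)
            if featurizer is not None:
                Xtr, Xte = featurizer(markers, tr, te)
            else:
                vals = markers.values if isinstance(markers, MarkerSet) else np.asarray(markers)
                Xtr, Xte = vals[tr], vals[te]
            try:
                model = make_model(model_spec)
                fit = model.fit(Xtr, y[tr])
                pas.append(predictive_ability(fit.predict(Xte).gebv, y[te]))
            except (EvaluationError, ValueError):
                skipped += 1
    if not pas:
        raise EvaluationError("no CV replicate could be evaluated")
    pas = np.array(pas)
    return EvaluationResult(
        replicate_pa=pas,
        mean_pa=float(pas.mean()),
        sd_pa=float(pas.std(ddof=1)) if len(pas) > 1 else 0.0,
        provenance={
            "k": scheme.k,
            "n_partitions": scheme.n_partitions,
            "n_samples": n,
            "skipped_replicates": skipped,
        },
    )


def run_app(
    train_markers,
    train_phenos,
    test_markers,
    test_phenos,
    model_spec,
) -> EvaluationResult:
    """Single-replicate across-population PA (markers harmonized upstream)."""
    ytr = np.asarray(train_phenos, dtype=float).ravel()
    yte = np.asarray(test_phenos, dtype=float).ravel()
    model = make_model(model_spec)
    fit = model.fit(train_markers, ytr)
    pred = fit.predict(test_markers)
    pa = predictive_ability(pred.gebv, yte)
    n_markers = (
        train_markers.n_features
        if isinstance(train_markers, MarkerSet)
        else np.asarray(train_markers).shape[1]
    )
    return EvaluationResult(
        replicate_pa=np.array([pa]),
        mean_pa=pa,
        sd_pa=0.0,
        provenance={
            "mode": "APP",
            "n_train": len(ytr),
            "n_test": len(yte),
            "shared_markers": n_markers,
        },
    )


def default_grid(n_shared: int, step: int = 500, cap: int | None = None) -> np.ndarray:
    """Marker-count grid {step, 2*step, ...} up to cap (default: all shared)."""
    top = min(cap, n_shared) if cap is not None else n_shared
    if top < step:
        raise EvaluationError(f"fewer shared markers ({n_shared}) than one grid step")
    return np.arange(step, top + 1, step)


@dataclass
class SubsampleCurve:
    grid: np.ndarray
    pa: dict[str, np.ndarray]  # model -> (n_bins, reps)
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    plateau: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, m in self.mean.items():
            for b, g in enumerate(self.grid):
                rows.append((model, int(g), m[b], self.sd[model][b]))
        return pd.DataFrame(rows, columns=["model", "n_markers", "mean_pa", "sd_pa"])


def marker_subsample_curve(
    train_gm: GenotypeMatrix,
    train_phenos,
    test_gm: GenotypeMatrix,
    test_phenos,
    model_specs: dict[str, object],
    grid=None,
    reps: int = 10,
    seed: int = 0,
) -> SubsampleCurve:
    """APP PA as a function of randomly subsampled shared-marker count.

    Inputs must be harmonized and imputed.  Per (bin, rep) an RNG stream
    derived from the master seed samples loci without replacement, both
    populations are featurized on that subset, the model refit from scratch,
    and PA measured on the test set.  Plateau = smallest bin whose mean PA
    reaches 99% of the best bin mean.
    """
    hm_train, hm_test = harmonize([train_gm, test_gm])
    n_shared = hm_train.n_loci
    if grid is None:
        grid = default_grid(n_shared)
    grid = np.asarray(grid, dtype=int)
    if grid.size == 0 or grid.max() > n_shared:
        raise EvaluationError(
            f"grid max {grid.max() if grid.size else 0} exceeds shared markers {n_shared}"
        )
    if np.any(np.diff(grid) <= 0):
        raise EvaluationError("grid must be strictly increasing")
    ytr = np.asarray(train_phenos, dtype=float).ravel()
    yte = np.asarray(test_phenos, dtype=float).ravel()
    pa = {m: np.zeros((len(grid), reps)) for m in model_specs}
    for b, size in enumerate(grid):
        for r in range(reps):
            rng = np.random.default_rng([seed, int(size), r])
            idx = np.sort(rng.choice(n_shared, size=size, replace=False))
            Xtr = snp_markers(hm_train.take_loci(idx))
            Xte = snp_markers(hm_test.take_loci(idx))
            for m, spec in model_specs.items():
                fit = make_model(spec).fit(Xtr, ytr)
                pa[m][b, r] = predictive_ability(fit.predict(Xte).gebv, yte)
    mean = {m: v.mean(axis=1) for m, v in pa.items()}
    sd = {m: v.std(axis=1, ddof=1) if reps > 1 else np.zeros(len(grid)) for m, v in pa.items()}
    plateau = {
        m: int(grid[np.flatnonzero(mean[m] >= 0.99 * mean[m].max())[0]])
        for m in model_specs
    }
    return SubsampleCurve(grid=grid, pa=pa, mean=mean, sd=sd, plateau=plateau)
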