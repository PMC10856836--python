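"""Mode-of-action statistics: two-way ANOVA, correlation PCA, separation.

The diagnosis logic works on the tidy measurement table produced by the
imaging stages: a balanced herbicide x time factorial feeds a fixed-effects
two-way ANOVA per spectral parameter; the six normalized parameters feed a
correlation-based PCA per timepoint and pooled; and clusters are scored by
a standardized centroid distance so "herbicide X separates at T hours" is
a quantitative statement rather than a visual one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.decomposition import PCA as _SKPCA

from .errors import ConfigurationError, UnbalancedDesignError
from .presets import CONTROL_TREATMENT, PARAMETERS

#: separation-score threshold above which a group counts as separated
DEFAULT_SEPARATION_THRESHOLD = 2.0
#: components retained for separation scoring (2-D ordinations)
DEFAULT_N_COMPONENTS = 2


@dataclass(frozen=True)
class AnovaResult:
    """Two-way fixed-effects ANOVA of one spectral parameter."""

    parameter: str
    F_herbicide: float
    F_time: float
    F_interaction: float
    p_herbicide: float
    p_time: float
    p_interaction: float
    df_herbicide: int
    df_time: int
    df_interaction: int
    df_residual: int
    ss_herbicide: float
    ss_time: float
    ss_interaction: float
    ss_residual: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameter,
            "source": ["herbicide", "time", "herbicide x time", "residual"],
            "df": [self.df_herbicide, self.df_time, self.df_interaction,
                   self.df_residual],
            "sum_sq": [self.ss_herbicide, self.ss_time, self.ss_interaction,
                       self.ss_residual],
            "F": [self.F_herbicide, self.F_time, self.F_interaction, np.nan],
            "p": [self.p_herbicide, self.p_time, self.p_interaction, np.nan],
        })


@dataclass
class PCAResult:
    """Correlation-based PCA of the spectral-parameter matrix."""

    scores: np.ndarray                    # (n_samples, n_kept)
    loadings: np.ndarray                  # (n_features, n_kept)
    eigenvalues: np.ndarray               # (n_kept,)
    explained_variance_fraction: np.ndarray
    feature_names: tuple[str, ...]
    sample_annotations: pd.DataFrame = field(default_factory=pd.DataFrame)


def two_way_anova(measurements: pd.DataFrame, parameter: str,
                  value_column: str = "normalized_value") -> AnovaResult:
    """Fixed-effects herbicide x time ANOVA with interaction.

    ``measurements`` is a tidy table with ``treatment``, ``hat`` and the
    value column; the design must be a balanced complete factorial (the
    assay's 7 treatments x 6 timepoints x 8 replicate wells). F is the
    effect mean square over the residual mean square.
    """
    df = measurements[measurements.parameter == parameter] \
        if "parameter" in measurements else measurements
    df = df[["treatment", "hat", value_column]].dropna().copy()
    if df.empty:
        raise ConfigurationError(f"no data for parameter {parameter!r}")
    counts = df.groupby(["treatment", "hat"], observed=True).size()
    n_t = df.treatment.nunique()
    n_h = df.hat.nunique()
    if len(counts) != n_t * n_h or counts.nunique() != 1:
        raise UnbalancedDesignError(
            "two_way_anova requires a balanced complete design (equal "
            "replicates in every treatment x time cell); got cell sizes "
            f"{sorted(counts.unique())} over {len(counts)} cells")
    if counts.iloc[0] < 2:
        raise UnbalancedDesignError("need >= 2 replicates per cell")

    model = smf.ols(f"{value_column} ~ C(treatment) * C(hat)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    herb = table.loc["C(treatment)"]
    time = table.loc["C(hat)"]
    inter = table.loc["C(treatment):C(hat)"]
    resid = table.loc["Residual"]
    return AnovaResult(
        parameter=parameter,
        F_herbicide=float(herb.F), F_time=float(time.F),
        F_interaction=float(inter.F),
        p_herbicide=float(herb["PR(>F)"]), p_time=float(time["PR(>F)"]),
        p_interaction=float(inter["PR(>F)"]),
        df_herbicide=int(herb.df), df_time=int(time.df),
        df_interaction=int(inter.df), df_residual=int(resid.df),
        ss_herbicide=float(herb.sum_sq), ss_time=float(time.sum_sq),
        ss_interaction=float(inter.sum_sq), ss_residual=float(resid.sum_sq),
    )


def correlation_pca(matrix, feature_names=None,
                    sample_annotations: pd.DataFrame | None = None
                    ) -> PCAResult:
    """PCA of the sample correlation matrix (columns standardized).

    Columns are centred and scaled to unit variance (ddof=1), so the
    component eigenvalues are those of the correlation matrix and sum to
    the number of retained variables. Constant columns are dropped with a
    warning. Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    if isinstance(matrix, pd.DataFrame):
        feature_names = tuple(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if feature_names is None:
            feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
        feature_names = tuple(feature_names)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("need a 2-D matrix with >= 2 samples")

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [feature_names[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(f"dropping constant column(s): {dropped}", stacklevel=2)
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ConfigurationError("all columns constant; PCA undefined")
    names = tuple(n for n, k in zip(feature_names, keep) if k)

    Z = (X - X.mean(axis=0)) / sd[keep]
    pca = _SKPCA(n_components=min(Z.shape), svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()          # orthonormal columns
    eigenvalues = pca.explained_variance_.copy()  # ddof=1: corr eigenvalues

    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    total = eigenvalues.sum()
    return PCAResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=eigenvalues,
        explained_variance_fraction=eigenvalues / total,
        feature_names=names,
        sample_annotations=(sample_annotations.reset_index(drop=True)
                            if sample_annotations is not None
                            else pd.DataFrame()),
    )


def pivot_parameter_matrix(measurements: pd.DataFrame,
                           parameters=PARAMETERS,
                           value_column: str = "normalized_value"
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot the tidy table to a samples x parameters matrix.

    Each sample is one (plate, well, hat). Returns (matrix, annotations);
    raises when a requested parameter column is absent.
    """
    keys = ["plate_id", "well_row", "well_col", "treatment", "hat"]
    wide = measurements.pivot_table(index=keys, columns="parameter",
                                    values=value_column, observed=True)
    missing = [p for p in parameters if p not in wide.columns]
    if missing:
        raise ConfigurationError(f"missing parameter column(s): {missing}")
    wide = wide[list(parameters)].dropna()
    annotations = wide.index.to_frame(index=False)
    return wide.reset_index(drop=True), annotations


def separation_report(pca: PCAResult, labels=None,
                      threshold: float = DEFAULT_SEPARATION_THRESHOLD,
                      n_components: int = DEFAULT_N_COMPONENTS
                      ) -> pd.DataFrame:
    """Score each group's separation from its nearest other group.

    For a pair of groups the score is the centroid distance in the
    retained component space divided by the pooled within-group RMS
    distance of the pair; a group's separation score is the minimum over
    all other groups, and ``separated`` is True when it exceeds
    ``threshold``. Singleton groups get a NaN score and a flag.
    """
    if labels is None:
        if "treatment" not in pca.sample_annotations:
            raise ConfigurationError("no group labels available")
        labels = pca.sample_annotations["treatment"].to_numpy()
    labels = np.asarray(labels)
    k = min(n_components, pca.scores.shape[1])
    S = pca.scores[:, :k]
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ConfigurationError("need >= 2 groups for a separation report")

    centroids = {g: S[labels == g].mean(axis=0) for g in groups}
    sq_resid = {g: float(((S[labels == g] - centroids[g]) ** 2).sum())
                for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}

    rows = []
    for g in groups:
        if sizes[g] < 2:
            rows.append(dict(treatment=g, separation_score=np.nan,
                             nearest_group=None, separated=False,
                             singleton=True))
            continue
        best, nearest = np.inf, None
        for h in groups:
            if h == g or sizes[h] < 2:
                continue
            d = float(np.linalg.norm(centroids[g] - centroids[h]))
            rms = np.sqrt((sq_resid[g] + sq_resid[h])
                          / (sizes[g] + sizes[h]))
            score = d / rms if rms > 0 else np.inf
            if score < best:
                best, nearest = score, h
        rows.append(dict(treatment=g, separation_score=best,
                         nearest_group=nearest,
                         separated=bool(best > threshold), singleton=False))
    return pd.DataFrame(rows)


def run_pooled_pca(measurements: pd.DataFrame,
                   parameters=PARAMETERS) -> PCAResult:
    """Correlation PCA of all timepoints pooled into one sample matrix."""
    matrix, annotations = pivot_parameter_matrix(measurements, parameters)
    return correlation_pca(matrix, sample_annotations=annotations)


def run_per_hat_pca(measurements: pd.DataFrame,
                    parameters=PARAMETERS) -> dict[int, PCAResult]:
    """Correlation PCA for each timepoint separately."""
    out: dict[int, PCAResult] = {}
    for hat, sub in measurements.groupby("hat"):
        matrix, annotations = pivot_parameter_matrix(sub, parameters)
        out[int(hat)] = correlation_pca(matrix,
                                        sample_annotations=annotations)
    return out


def separation_timeline(measurements: pd.DataFrame,
                        threshold: float = DEFAULT_SEPARATION_THRESHOLD,
                        n_components: int = DEFAULT_N_COMPONENTS,
                        parameters=PARAMETERS) -> pd.DataFrame:
    """Per-timepoint separation scores for every treatment.

    Returns one row per (hat, treatment) with the separation score, the
    nearest other group, and the separated flag -- the quantitative analogue
    of reading cluster separation off per-timepoint ordinations.
    """
    frames = []
    for hat, pca in sorted(run_per_hat_pca(measurements, parameters).items()):
        rep = separation_report(pca, threshold=threshold,
                                n_components=n_components)
        rep.insert(0, "hat", hat)
        frames.append(rep)
    return pd.concat(frames, ignore_index=True)


def first_separation_hat(timeline: pd.DataFrame) -> dict[str, float]:
    """Earliest timepoint at which each treatment is separated (NaN if never)."""
    out: dict[str, float] = {}
    for treatment, sub in timeline.groupby("treatment"):
        hit = sub[sub.separated]
        out[str(treatment)] = float(hit.hat.min()) if not hit.empty else np.nan
    return out
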