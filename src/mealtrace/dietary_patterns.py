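"""A-posteriori dietary patterns: PCA with varimax rotation on food-group intakes.

The participant x food-group matrix holds mean grams/day per group over the
recorded days (25 columns: the codebook minus "other" and "supplements").
Because many groups have structural zeros (most participants report no legumes
or nuts at all over four days) and gram scales span orders of magnitude,
intakes are log(x+1)-transformed and, by default, standardised to zero mean /
unit variance within each analysis stratum before extraction — i.e.
correlation-matrix PCA. Components with a pre-rotation eigenvalue above 1.0
are varimax-rotated (orthogonal, Kaiser row-normalised) for interpretation;
only components above 1.5 feed downstream models. Adherence to each retained
pattern is the rotated component score, split into sample tertiles within sex.

``DietaryPatternAnalysis`` is a scikit-learn style transformer: ``fit`` learns
column scaling, eigenvalues and rotated loadings; ``transform`` returns
per-participant pattern scores. Sex-stratified analyses fit one estimator per
stratum so scaling parameters are never shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .codebook import DEFAULT_CODEBOOK, FoodGroupCodebook
from .config import PCAOptions


class DietaryPatternError(ValueError):
    pass


@dataclass
class FoodGroupMatrix:
    """Participant x food-group intake matrix with its transform state."""

    data: pd.DataFrame  # index participant_id, columns = PCA food groups
    transform: str = "raw"  # "raw" | "log"
    log_offset: float = 1.0


def build_foodgroup_matrix(
    entries: pd.DataFrame,
    participants: pd.DataFrame,
    codebook: FoodGroupCodebook = DEFAULT_CODEBOOK,
) -> FoodGroupMatrix:
    """Mean g/day per PCA food group for each retained participant.

    Zeros (not missing) for groups never consumed; unknown codes are an error.
    """
    codebook.validate_codes(entries["food_group"].unique())
    n_days = entries.groupby("participant_id")["day"].nunique()
    totals = (
        entries.groupby(["participant_id", "food_group"])["weight_g"].sum().unstack(fill_value=0.0)
    )
    pids = list(participants["participant_id"])
    mat = totals.reindex(index=pids, columns=list(codebook.pca_groups), fill_value=0.0)
    mat = mat.div(n_days.reindex(pids), axis=0).fillna(0.0)
    mat.index.name = "participant_id"
    return FoodGroupMatrix(mat, "raw")


def log_transform(matrix: FoodGroupMatrix, offset: float = 1.0) -> FoodGroupMatrix:
    """log(x + offset) gram transform; ln(0+1)=0 keeps structural zeros at zero.

    Applying the transform twice is an error.
    """
    if matrix.transform != "raw":
        raise DietaryPatternError("matrix is already log-transformed")
    if offset <= 0:
        raise DietaryPatternError("log offset must be positive")
    return FoodGroupMatrix(np.log(matrix.data + offset), "log", offset)


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Returns ``(rotated, rotation)`` with ``rotated = loadings @ rotation`` and
    ``rotation`` orthogonal. With fewer than two columns the rotation is the
    identity. Kaiser normalisation divides rows by their communalities during
    rotation (restored afterwards).
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    comm = np.sqrt((L**2).sum(axis=1))
    if kaiser_normalize:
        safe = np.where(comm > 0, comm, 1.0)
        L = L / safe[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Z = L @ R
        B = L.T @ (Z**3 - Z * (Z**2).sum(axis=0) / p)
        U, s, Vt = np.linalg.svd(B)
        R = U @ Vt
        var_new = s.sum()
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    rotated = L @ R
    if kaiser_normalize:
        rotated = rotated * np.where(comm > 0, comm, 1.0)[:, None]
    return rotated, R


def _fix_signs(loadings: np.ndarray, scores: np.ndarray | None = None):
    """Force each component's largest-|loading| entry positive (backend-stable)."""
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    if scores is not None:
        scores = scores * flip
    return loadings, scores, flip


class DietaryPatternAnalysis(BaseEstimator, TransformerMixin):
    """PCA dietary patterns with varimax rotation and eigenvalue retention.

    Parameters
    ----------
    graphical_eigenvalue : float, default 1.0
        Pre-rotation eigenvalue above which a component is retained for
        rotation and graphical presentation.
    analysis_eigenvalue : float, default 1.5
        Pre-rotation eigenvalue above which a component also enters downstream
        models. Always a subset of the graphical set.
    standardize : bool, default True
        Scale columns to unit variance (correlation-matrix PCA). Centring
        always happens.
    kaiser_normalize, varimax_tol, varimax_max_iter
        Varimax settings.

    Attributes
    ----------
    eigenvalues_ : ndarray
        All pre-rotation eigenvalues (unit-variance metric; they sum to the
        number of analysed columns when ``standardize=True``).
    loadings_ : DataFrame, groups x retained components
        Varimax-rotated loadings (component correlations with the
        standardised variables), sign-fixed.
    pct_variance_ : ndarray
        Percent of total variance per rotated component (post-rotation).
    n_retained_graphical_, n_retained_analysis_ : int
    dropped_columns_ : list of zero-variance columns removed before PCA.
    """

    def __init__(
        self,
        graphical_eigenvalue: float = 1.0,
        analysis_eigenvalue: float = 1.5,
        standardize: bool = True,
        kaiser_normalize: bool = True,
        varimax_tol: float = 1e-8,
        varimax_max_iter: int = 1000,
    ):
        self.graphical_eigenvalue = graphical_eigenvalue
        self.analysis_eigenvalue = analysis_eigenvalue
        self.standardize = standardize
        self.kaiser_normalize = kaiser_normalize
        self.varimax_tol = varimax_tol
        self.varimax_max_iter = varimax_max_iter

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, FoodGroupMatrix):
            if X.transform != "log":
                raise DietaryPatternError("apply log_transform before pattern analysis")
            return X.data
        return pd.DataFrame(X)

    def fit(self, X, y=None):
        df = self._as_frame(X)
        if df.shape[0] < 3:
            raise DietaryPatternError("need at least 3 participants for PCA")
        sd = df.std(ddof=1)
        dropped = list(df.columns[sd == 0])
        if dropped:
            warnings.warn(f"dropping zero-variance food groups before PCA: {dropped}")
            df = df.drop(columns=dropped)
            sd = sd.drop(index=dropped)
        self.columns_ = list(df.columns)
        self.dropped_columns_ = dropped
        self.mean_ = df.mean().to_numpy()
        self.scale_ = sd.to_numpy() if self.standardize else np.ones(df.shape[1])
        Z = (df.to_numpy() - self.mean_) / self.scale_
        # eigen-decomposition of the (co)variance of the scaled data, ddof=1
        cov = Z.T @ Z / (Z.shape[0] - 1)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        self.eigenvalues_ = eigval
        k = int(np.sum(eigval > self.graphical_eigenvalue))
        k = max(k, 1)
        self.n_retained_graphical_ = k
        self.n_retained_analysis_ = int(
            np.sum(eigval > self.analysis_eigenvalue)
        )
        raw_loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
        rotated, R = varimax(
            raw_loadings,
            kaiser_normalize=self.kaiser_normalize,
            tol=self.varimax_tol,
            max_iter=self.varimax_max_iter,
        )
        rotated, _, flip = _fix_signs(rotated)
        self._score_basis = (eigvec[:, :k] / np.sqrt(eigval[:k])) @ R * flip
        names = [f"DP{i + 1}" for i in range(k)]
        # order rotated components by explained variance (sum of squared loadings)
        ssl = (rotated**2).sum(axis=0)
        order2 = np.argsort(ssl)[::-1]
        rotated = rotated[:, order2]
        self._score_basis = self._score_basis[:, order2]
        ssl = ssl[order2]
        self.loadings_ = pd.DataFrame(rotated, index=self.columns_, columns=names)
        self.pct_variance_ = 100.0 * ssl / len(self.columns_)
        self.pct_variance_unrotated_ = 100.0 * eigval / len(self.columns_)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Rotated, unit-variance pattern scores for each participant."""
        check_is_fitted(self, "loadings_")
        df = self._as_frame(X)
        df = df.reindex(columns=self.columns_)
        Z = (df.to_numpy() - self.mean_) / self.scale_
        scores = Z @ self._score_basis
        return pd.DataFrame(scores, index=df.index, columns=list(self.loadings_.columns))

    @property
    def analysis_components_(self) -> list[str]:
        """Names of components with eigenvalue above the analysis threshold."""
        check_is_fitted(self, "loadings_")
        return list(self.loadings_.columns[: self.n_retained_analysis_])


def adherence_tertiles(scores: pd.Series) -> pd.Series:
    """Sample tertiles (1=lowest adherence) of one pattern score.

    Participants are ranked with a stable sort (ties broken by input order)
    and split into three nearly equal groups, the earlier groups taking the
    extra member when n is not divisible by 3 (n=10 -> 4/3/3). Degenerate
    all-equal scores put everyone in tertile 1 with a warning.
    """
    n = len(scores)
    if n < 3:
        raise DietaryPatternError("need at least 3 observations for tertiles")
    values = scores.to_numpy(dtype=float)
    if np.ptp(values) == 0:
        warnings.warn("all scores equal; assigning everyone to tertile 1")
        return pd.Series(1, index=scores.index, dtype=int)
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    for t, chunk in enumerate(np.array_split(np.arange(n), 3), start=1):
        labels[order[chunk]] = t
    return pd.Series(labels, index=scores.index, dtype=int)


@dataclass
class DietaryPatternResult:
    """Pattern-analysis output for one stratum."""

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    scores: pd.DataFrame
    analysis_components: list[str]
    tertiles: pd.DataFrame = field(default_factory=pd.DataFrame)
    estimator: DietaryPatternAnalysis | None = None


def pca_varimax(
    matrix: FoodGroupMatrix,
    participants: pd.DataFrame | None = None,
    options: PCAOptions | None = None,
) -> dict[str, DietaryPatternResult]:
    """Sex-stratified dietary patterns (one fitted estimator per stratum).

    When ``participants`` is None a single stratum ``"all"`` is analysed.
    """
    options = options or PCAOptions()
    logm = matrix if matrix.transform == "log" else log_transform(matrix, options.log_offset)
    if participants is None:
        strata = {"all": list(logm.data.index)}
    else:
        strata = {
            sex: list(g["participant_id"]) for sex, g in participants.groupby("sex")
        }
    out: dict[str, DietaryPatternResult] = {}
    for stratum, pids in strata.items():
        sub = FoodGroupMatrix(logm.data.loc[pids], "log", logm.log_offset)
        est = DietaryPatternAnalysis(
            graphical_eigenvalue=options.graphical_eigenvalue,
            analysis_eigenvalue=options.analysis_eigenvalue,
            standardize=options.standardize,
            kaiser_normalize=options.kaiser_normalize,
            varimax_tol=options.varimax_tol,
            varimax_max_iter=options.varimax_max_iter,
        ).fit(sub)
        scores = est.transform(sub)
        tert = pd.DataFrame(
            {c: adherence_tertiles(scores[c]) for c in est.analysis_components_},
            index=scores.index,
        )
        out[stratum] = DietaryPatternResult(
            loadings=est.loadings_,
            eigenvalues=est.eigenvalues_,
            pct_variance=est.pct_variance_,
            scores=scores,
            analysis_components=est.analysis_components_,
            tertiles=tert,
            estimator=est,
        )
    return out


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def best_congruence(
    estimated: pd.DataFrame | np.ndarray, truth: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """Per-truth-factor best |congruence| over estimated components.

    Handles sign and permutation indeterminacy by matching each planted factor
    with its most congruent estimated component (greedy, without replacement).
    """
    E = np.asarray(estimated, dtype=float)
    T = np.asarray(truth, dtype=float)
    c = np.zeros((T.shape[1], E.shape[1]))
    for i in range(T.shape[1]):
        for j in range(E.shape[1]):
            c[i, j] = abs(tucker_congruence(T[:, i], E[:, j]))
    out = np.zeros(T.shape[1])
    used: set[int] = set()
    for i in np.argsort(-c.max(axis=1)):
        j = int(np.argmax([c[i, j] if j not in used else -1 for j in range(E.shape[1])]))
        out[i] = c[i, j]
        used.add(j)
    return out
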