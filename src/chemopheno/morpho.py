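"""Morphometric stage: synthetic character tables, group statistics,
best-subset selection and linear discriminant analysis.

Twelve quantitative characters are recorded per plant:

X1  root diameter [cm]          X7   ray flower length [cm]
X2  stem height [cm]            X8   ray flowers per head [count]
X3  leaf length [cm]            X9   disc flower length [cm]
X4  leaf width [cm]             X10  disc flowers per head [count]
X5  involucral bract length [cm] X11 flower head diameter [cm]
X6  involucral bracts per capitulum [count]  X12 capitula per plant [count]

The default species profiles are synthetic: they encode the qualitative
structure reported for the five taxa (root diameter separating the
genera; leaf width homogeneous within Senecio; bract/ray/disc counts
mutually positively correlated and negatively correlated with stem
height; capitula count far noisier than the rest) with magnitudes chosen
as botanically plausible, not measured values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps

__all__ = [
    "SPECIES",
    "CHARACTERS",
    "COUNT_CHARACTERS",
    "SpeciesProfile",
    "default_profiles",
    "generate_morphometrics",
    "descriptive_stats",
    "correlation_matrix",
    "group_tests",
    "best_subset",
    "LDAModel",
    "lda_fit",
    "lda_project",
    "lda_predict",
    "confusion_matrix",
    "train_test_split_indices",
    "evaluate_splits",
]

SPECIES = ["S_hercynicus", "S_ovatus", "S_rupestris", "J_pancicii", "J_maritima"]
CHARACTERS = [f"X{i}" for i in range(1, 13)]
#: integer-valued characters (organ counts)
COUNT_CHARACTERS = ("X6", "X8", "X10", "X12")


def default_correlation() -> np.ndarray:
    """Shared within-species correlation structure over X1..X12."""
    R = np.eye(12)

    def set_(a: int, b: int, r: float) -> None:
        R[a - 1, b - 1] = R[b - 1, a - 1] = r

    set_(2, 3, 0.60)   # taller plants bear longer leaves
    set_(6, 8, 0.60)   # organ counts rise and fall together
    set_(6, 10, 0.55)
    set_(8, 10, 0.65)
    set_(2, 6, -0.40)  # taller plants carry fewer-flowered heads
    set_(2, 8, -0.40)
    set_(2, 10, -0.40)
    np.linalg.cholesky(R)  # raises if not positive definite
    return R


@dataclass(frozen=True)
class SpeciesProfile:
    """Mean vector, SD vector and correlation structure for one species."""

    species: str
    mean: np.ndarray
    sd: np.ndarray
    correlation: np.ndarray = field(default_factory=default_correlation)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != (12,) or self.sd.shape != (12,):
            raise ValueError("mean and sd must have 12 entries (X1..X12)")
        if (self.sd < 0).any():
            raise ValueError("SDs must be non-negative")
        eig = np.linalg.eigvalsh(self.correlation)
        if eig.min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")

    def covariance(self) -> np.ndarray:
        D = np.diag(self.sd)
        return D @ self.correlation @ D


def default_profiles() -> list[SpeciesProfile]:
    """Synthetic per-species profiles (see module docstring)."""
    means = {
        #                X1    X2   X3   X4   X5    X6   X7    X8    X9    X10  X11  X12
        "S_hercynicus": [0.55, 95,  14,  3.0, 0.80, 8.0, 1.15, 6.0,  0.85, 20,  1.9, 25],
        "S_ovatus":     [0.50, 90,  13,  3.1, 0.78, 9.0, 1.05, 7.5,  0.75, 22,  1.7, 30],
        "S_rupestris":  [0.45, 40,  6,   2.9, 0.50, 13,  0.70, 12,   0.65, 35,  2.2, 15],
        "J_pancicii":   [1.00, 85,  12,  1.6, 0.75, 10,  1.00, 10,   0.70, 30,  2.0, 12],
        "J_maritima":   [1.10, 45,  7,   0.9, 0.52, 12,  0.72, 13,   0.60, 40,  2.5, 40],
    }
    cv = np.array([0.12] * 11 + [0.45])  # capitula count is far noisier
    return [
        SpeciesProfile(species=s, mean=np.array(m, dtype=float),
                       sd=np.array(m, dtype=float) * cv)
        for s, m in means.items()
    ]


def generate_morphometrics(
    profiles: list[SpeciesProfile] | None = None,
    n_per_species: int = 15,
    seed: int = 0,
    discretize: bool = True,
) -> pd.DataFrame:
    """Seeded multivariate-normal draws per species.

    With ``discretize`` (the default), count characters are rounded to
    integers and truncated at 1 -- note rounding slightly attenuates their
    correlations relative to the profile -- and length characters are
    truncated just above zero. Returns a DataFrame with a ``species``
    column followed by X1..X12.
    """
    profiles = profiles if profiles is not None else default_profiles()
    rng = np.random.default_rng(seed)
    frames = []
    for prof in profiles:
        cov = prof.covariance()
        if np.allclose(cov, 0):
            X = np.tile(prof.mean, (n_per_species, 1))
        else:
            X = rng.multivariate_normal(
                prof.mean, cov, size=n_per_species, method="svd"
            )
        df = pd.DataFrame(X, columns=CHARACTERS)
        if discretize:
            for c in COUNT_CHARACTERS:
                df[c] = np.maximum(1, np.rint(df[c])).astype(int)
            for c in CHARACTERS:
                if c not in COUNT_CHARACTERS:
                    df[c] = np.maximum(df[c], 1e-3)
        df.insert(0, "species", prof.species)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def descriptive_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and %CV per species x character (%CV = 100*SD/mean)."""
    rows = []
    for sp, g in table.groupby("species", sort=False):
        if len(g) < 2:
            raise ValueError(f"species {sp!r} needs >=2 observations")
        for c in CHARACTERS:
            mean = g[c].mean()
            sd = g[c].std(ddof=1)
            if mean == 0 and sd > 0:
                raise ValueError(f"%CV undefined: zero mean with nonzero SD for {sp}/{c}")
            rows.append((sp, c, mean, sd, 100.0 * sd / mean if mean != 0 else 0.0))
    return pd.DataFrame(rows, columns=["species", "character", "mean", "sd", "cv_percent"])


def correlation_matrix(table: pd.DataFrame, alpha: float = 0.05):
    """Pearson correlations over all plants with per-pair significance.

    Returns (correlation DataFrame, p-value DataFrame, boolean
    significance DataFrame at ``alpha``).
    """
    X = table[CHARACTERS]
    if len(X) < 3:
        raise ValueError("need >=3 rows for correlation")
    if (X.std(ddof=1) == 0).any():
        bad = [c for c in CHARACTERS if X[c].std(ddof=1) == 0]
        raise ValueError(f"zero-variance columns: {bad}")
    corr = pd.DataFrame(np.eye(12), index=CHARACTERS, columns=CHARACTERS)
    pval = pd.DataFrame(np.zeros((12, 12)), index=CHARACTERS, columns=CHARACTERS)
    for a, b in itertools.combinations(CHARACTERS, 2):
        r, p = sps.pearsonr(X[a], X[b])
        corr.loc[a, b] = corr.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
    return corr, pval, pval < alpha


def _scatter_matrices(table: pd.DataFrame, variables: list[str]):
    X = table[variables].to_numpy(dtype=float)
    groups = table["species"].to_numpy()
    grand = X.mean(axis=0)
    W = np.zeros((len(variables), len(variables)))
    B = np.zeros_like(W)
    for g in pd.unique(groups):
        Xg = X[groups == g]
        mg = Xg.mean(axis=0)
        W += (Xg - mg).T @ (Xg - mg)
        B += len(Xg) * np.outer(mg - grand, mg - grand)
    return W, B


def _wilks_f(lmbda: float, p: int, g: int, n: int):
    """Rao's F approximation for Wilks' lambda."""
    df1 = p * (g - 1)
    denom = p**2 + (g - 1) ** 2 - 5
    t = math.sqrt((p**2 * (g - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    m = n - 1 - (p + g) / 2
    df2 = m * t - df1 / 2 + 1
    lam_t = lmbda ** (1.0 / t)
    F = (1 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else math.inf
    pval = float(sps.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
    return F, df1, df2, pval


@dataclass
class GroupTestResult:
    """MANOVA, Kruskal-Wallis and Bonferroni post-hoc summaries."""

    manova: dict
    per_character: pd.DataFrame
    posthoc: dict[str, pd.DataFrame]


def group_tests(table: pd.DataFrame, alpha: float = 0.05) -> GroupTestResult:
    """Parametric and rank-based tests of species effect on each character.

    The multivariate test is Wilks' lambda = det(W)/det(W+B) over all 12
    characters with Rao's F approximation. Per character, the univariate
    Wilks (= SSW/SST with its exact F) and the tie-corrected
    Kruskal-Wallis H are reported; the post-hoc matrices hold pairwise
    two-sample t-test p-values multiplied by the number of comparisons
    and capped at 1.
    """
    species = list(pd.unique(table["species"]))
    g = len(species)
    n = len(table)
    if g < 2 or (table.groupby("species").size() < 2).any():
        raise ValueError("need >=2 groups with >=2 observations each")

    W, B = _scatter_matrices(table, CHARACTERS)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular within-class scatter matrix")
    lmbda = float(np.exp(logdet_w - logdet_t))
    F, df1, df2, pval = _wilks_f(lmbda, len(CHARACTERS), g, n)
    manova = {"wilks_lambda": lmbda, "F": F, "df1": df1, "df2": df2, "p": pval}

    rows = []
    posthoc: dict[str, pd.DataFrame] = {}
    n_cmp = g * (g - 1) // 2
    for c in CHARACTERS:
        samples = [table.loc[table["species"] == s, c].to_numpy() for s in species]
        ssw = sum(((x - x.mean()) ** 2).sum() for x in samples)
        sst = ((table[c] - table[c].mean()) ** 2).sum()
        lam_c = float(ssw / sst) if sst > 0 else 1.0
        F_c = ((sst - ssw) / (g - 1)) / (ssw / (n - g)) if ssw > 0 else math.inf
        p_c = float(sps.f.sf(F_c, g - 1, n - g)) if math.isfinite(F_c) else 0.0
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            H, p_kw = 0.0, 1.0
        else:
            H, p_kw = sps.kruskal(*samples)
        rows.append((c, lam_c, F_c, p_c, float(H), float(p_kw)))

        mat = pd.DataFrame(np.ones((g, g)), index=species, columns=species)
        for i, j in itertools.combinations(range(g), 2):
            if np.ptp(np.concatenate([samples[i], samples[j]])) == 0:
                p_t = 1.0
            else:
                p_t = sps.ttest_ind(samples[i], samples[j], equal_var=True).pvalue
            p_adj = min(1.0, float(p_t) * n_cmp)
            mat.iloc[i, j] = mat.iloc[j, i] = p_adj
        np.fill_diagonal(mat.values, np.nan)
        posthoc[c] = mat

    per_character = pd.DataFrame(
        rows, columns=["character", "wilks_lambda", "F", "p_manova", "H", "p_kruskal"]
    ).set_index("character")
    return GroupTestResult(manova=manova, per_character=per_character, posthoc=posthoc)


# ---------------------------------------------------------------------------
# best-subset selection


@dataclass
class SubsetSelectionResult:
    """Exhaustive subset search over the 12 characters.

    ``table`` has one row per subset with RSS, adjusted R2, Mallow's Cp,
    BIC and Wilks' lambda; ``best_per_size`` maps metric -> {size: row};
    ``chosen`` is the BIC-optimal subset.
    """

    table: pd.DataFrame
    best_per_size: dict[str, dict[int, tuple[str, ...]]]
    chosen: tuple[str, ...]


def best_subset(table: pd.DataFrame, max_exhaustive: int = 20) -> SubsetSelectionResult:
    """Score every non-empty predictor subset against species membership.

    The species response is one-hot coded (q = number of species) and a
    linear model with intercept is fitted per indicator; RSS is summed
    over indicators. Metrics are reported on a per-response scale so the
    classical identities hold (the full model's Cp equals its predictor
    count + 1). Wilks' lambda over the subset is included as the
    classification-oriented ranking.
    """
    p_all = len(CHARACTERS)
    if p_all > max_exhaustive:
        raise ValueError(f"exhaustive search capped at {max_exhaustive} predictors")
    species = pd.unique(table["species"])
    q = len(species)
    n = len(table)
    Y = pd.get_dummies(table["species"]).astype(float).to_numpy()
    X_all = table[CHARACTERS].to_numpy(dtype=float)
    TSS = float(((Y - Y.mean(axis=0)) ** 2).sum())

    def rss_of(cols: tuple[int, ...]) -> float:
        M = np.column_stack([np.ones(n), X_all[:, cols]])
        resid = Y - M @ np.linalg.lstsq(M, Y, rcond=None)[0]
        return float((resid**2).sum())

    full = tuple(range(p_all))
    rss_full = rss_of(full)
    s2 = rss_full / (q * (n - p_all - 1))

    rows = []
    for size in range(1, p_all + 1):
        for cols in itertools.combinations(range(p_all), size):
            rss = rss_of(cols)
            p = size
            adj_r2 = 1 - (rss / (q * (n - p - 1))) / (TSS / (q * (n - 1)))
            cp = rss / (q * s2) - n + 2 * (p + 1)
            bic = n * math.log(rss / (n * q)) + (p + 1) * math.log(n)
            names = tuple(CHARACTERS[i] for i in cols)
            W, B = _scatter_matrices(table, list(names))
            sw, lw = np.linalg.slogdet(W)
            st, lt = np.linalg.slogdet(W + B)
            wilks = float(np.exp(lw - lt)) if sw > 0 and st > 0 else np.nan
            rows.append((names, size, rss, adj_r2, cp, bic, wilks))

    tab = pd.DataFrame(
        rows, columns=["variables", "size", "rss", "adj_r2", "cp", "bic", "wilks_lambda"]
    )
    best_per_size: dict[str, dict[int, tuple[str, ...]]] = {}
    for metric, minimize in [("rss", True), ("adj_r2", False), ("cp", True),
                             ("bic", True), ("wilks_lambda", True)]:
        per = {}
        for size, g_ in tab.groupby("size"):
            idx = g_[metric].idxmin() if minimize else g_[metric].idxmax()
            per[int(size)] = tuple(g_.loc[idx, "variables"])
        best_per_size[metric] = per
    chosen = tuple(tab.loc[tab["bic"].idxmin(), "variables"])
    return SubsetSelectionResult(table=tab, best_per_size=best_per_size, chosen=chosen)


# ---------------------------------------------------------------------------
# linear discriminant analysis


@dataclass
class LDAModel:
    """Fisher discriminant model with pooled within-class covariance."""

    variables: list[str]
    classes: list[str]
    class_means: pd.DataFrame
    pooled_cov: np.ndarray
    scalings: np.ndarray  # columns LD1, LD2, ... normalized v' Sw v = 1
    priors: np.ndarray
    grand_mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scalings.shape[1]


def lda_fit(
    table: pd.DataFrame,
    variables: list[str] | tuple[str, ...] | None = None,
    priors: np.ndarray | None = None,
) -> LDAModel:
    """Fit LDA from class means and pooled within-class covariance.

    Discriminant directions are the leading eigenvectors of the
    generalized problem B v = lambda W v (equivalently W^-1 B), at most
    (classes - 1) of them; prediction uses the smallest Mahalanobis
    distance to a class mean under the pooled covariance, shifted by
    -2 log(prior). Raises on a singular pooled covariance, naming the
    collinear variables.
    """
    variables = list(variables) if variables is not None else list(CHARACTERS)
    classes = list(pd.unique(table["species"]))
    g = len(classes)
    n = len(table)
    X = table[variables].to_numpy(dtype=float)
    y = table["species"].to_numpy()

    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    grand = X.mean(axis=0)
    W = np.zeros((len(variables), len(variables)))
    B = np.zeros_like(W)
    for c, m in zip(classes, means):
        Xg = X[y == c]
        W += (Xg - m).T @ (Xg - m)
        B += len(Xg) * np.outer(m - grand, m - grand)
    Sw = W / (n - g)

    if np.linalg.matrix_rank(Sw) < len(variables):
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise np.linalg.LinAlgError(
            "singular pooled covariance; most collinear variables: "
            f"{variables[i]} and {variables[j]}"
        )

    evals, evecs = sla.eigh(B / (n - g), Sw)
    order = np.argsort(evals)[::-1][: min(g - 1, len(variables))]
    scalings = evecs[:, order]
    for m in range(scalings.shape[1]):
        pivot = np.argmax(np.abs(scalings[:, m]))
        if scalings[pivot, m] < 0:
            scalings[:, m] *= -1

    priors = (
        np.full(g, 1.0 / g) if priors is None else np.asarray(priors, dtype=float)
    )
    if priors.shape != (g,) or not math.isclose(priors.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("priors must be one probability per class summing to 1")

    return LDAModel(
        variables=variables,
        classes=classes,
        class_means=pd.DataFrame(means, index=classes, columns=variables),
        pooled_cov=Sw,
        scalings=scalings,
        priors=priors,
        grand_mean=grand,
    )


def lda_project(model: LDAModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Discriminant scores (LD1, LD2, ...) for new observations."""
    X = rows[model.variables].to_numpy(dtype=float)
    scores = (X - model.grand_mean) @ model.scalings
    return pd.DataFrame(
        scores, index=rows.index,
        columns=[f"LD{m + 1}" for m in range(model.n_components)],
    )


def lda_predict(model: LDAModel, rows: pd.DataFrame) -> list[str]:
    """Class labels by minimal prior-adjusted Mahalanobis distance."""
    X = rows[model.variables].to_numpy(dtype=float)
    VI = np.linalg.inv(model.pooled_cov)
    scores = np.empty((len(X), len(model.classes)))
    for ci, c in enumerate(model.classes):
        diff = X - model.class_means.loc[c].to_numpy()
        scores[:, ci] = np.einsum("ij,jk,ik->i", diff, VI, diff) - 2 * np.log(
            model.priors[ci]
        )
    return [model.classes[i] for i in scores.argmin(axis=1)]


def confusion_matrix(true_labels, predicted_labels, classes: list[str]) -> pd.DataFrame:
    """Rows = true class, columns = predicted class."""
    cm = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(true_labels, predicted_labels):
        cm.loc[t, p] += 1
    return cm


def train_test_split_indices(n: int, test_fraction: float, seed: int):
    """Seeded random split; returns (train indices, test indices)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def evaluate_splits(
    table: pd.DataFrame,
    variables: list[str] | tuple[str, ...],
    n_splits: int = 50,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> list[float]:
    """Test-set accuracies over repeated seeded random 80/20 splits."""
    accuracies = []
    for k in range(n_splits):
        tr, te = train_test_split_indices(len(table), test_fraction, seed * 10_000 + k)
        train, test = table.iloc[tr], table.iloc[te]
        if train["species"].nunique() < table["species"].nunique():
            continue  # degenerate split without all classes
        model = lda_fit(train, variables)
        pred = lda_predict(model, test)
        accuracies.append(float(np.mean(np.array(pred) == test["species"].to_numpy())))
    return accuracies
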