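"""Statistical evaluation of residue-impact matrices.

Scores
------
From an n x n residue-impact matrix X, each residue i gets a *target*
score (row mean of X[i, :], impact received) and a *source* score (column
mean of X[:, i], impact exerted), optionally on absolute values.

Tests
-----
* categorical (Mann-Whitney U, two-sided): pooled per-residue scores split
  by interactivity (labelled 1 vs 0), aromaticity (F/Y/W vs rest) and
  acidity vs basicity (D/E vs H/K/R residues only);
* numerical (Kendall tau-b, two-sided): the 20-dimensional per-amino-acid
  mean score vector against hydrophobicity, molecular mass, van der Waals
  volume and dipole moment.

p < alpha (default 0.05) counts as a pass; no multiple-testing correction
is applied, matching the evaluation design the reference tables follow.

Summaries
---------
Pass counts by attribution method x model x test kind, by method x test
type, by model x test type, an embedding-vs-prediction pass cross-tab, and
an exclusivity analysis of which tests only a single model passes.  The
same summarizers accept either freshly computed results or the packaged
reference p-value tables.

Also here: distance profiles (mean |impact| against sequence separation)
and the structured-vs-random SVM separability check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import numpy as np
import pandas as pd
import scipy.stats
from skimage.transform import resize
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .aggregate import ResidueImpactMatrix
from .data import (
    AA_ALPHABET,
    ACIDIC,
    AROMATIC,
    BASIC,
    CATEGORICAL_PROPERTIES,
    NUMERICAL_PROPERTIES,
    ReportedPValueTable,
    generate_random_matrix,
)

ALPHA_DEFAULT = 0.05
TEST_TYPES = ("target", "source", "embedding", "prediction")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-table style)."""
    return int(floor(x + 0.5)) if x >= 0 else -int(floor(-x + 0.5))


# ---------------------------------------------------------------------------
# residue and amino-acid scores
# ---------------------------------------------------------------------------

@dataclass
class ResidueScoreSet:
    """Per-residue target/source scores for one protein's impact matrix."""

    protein: str
    sequence: str
    target_scores: np.ndarray  # row means: impact received
    source_scores: np.ndarray  # column means: impact exerted
    transform: str
    interaction_labels: np.ndarray | None = None


def residue_scores(X, sequence: str, transform: str = "signed",
                   protein: str = "", interaction_labels=None) -> ResidueScoreSet:
    """Row/column mean scores per residue under a signed or absolute transform."""
    if isinstance(X, ResidueImpactMatrix):
        X = X.X
    X = np.asarray(X, dtype=np.float64)
    if transform == "absolute":
        X = np.abs(X)
    elif transform != "signed":
        raise ValueError(f"transform must be 'signed' or 'absolute', got {transform!r}")
    if X.shape[0] != len(sequence):
        raise ValueError("matrix size does not match sequence length")
    return ResidueScoreSet(
        protein=protein,
        sequence=sequence,
        target_scores=X.mean(axis=1),
        source_scores=X.mean(axis=0),
        transform=transform,
        interaction_labels=(None if interaction_labels is None
                            else np.asarray(interaction_labels, dtype=np.int8)),
    )


def amino_acid_mean_scores(score_sets: list[ResidueScoreSet], role: str) -> np.ndarray:
    """Mean score per amino-acid letter pooled over all residues of all proteins.

    Returns a 20-vector in alphabetical letter order; letters absent from
    the corpus are NaN.
    """
    if not score_sets:
        raise ValueError("empty corpus")
    if role not in ("target", "source"):
        raise ValueError(f"role must be 'target' or 'source', got {role!r}")
    sums = np.zeros(20)
    counts = np.zeros(20, dtype=np.int64)
    for s in score_sets:
        scores = s.target_scores if role == "target" else s.source_scores
        for letter, v in zip(s.sequence, scores):
            k = AA_ALPHABET.index(letter)
            sums[k] += v
            counts[k] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


# ---------------------------------------------------------------------------
# the two nonparametric tests
# ---------------------------------------------------------------------------

_EXACT_MW_LIMIT = 200  # n1*n2 at or below this: exact null enumeration


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact null enumeration for small samples without ties (n1*n2 <= 200),
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= _EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b with tie correction, two-sided p.

    Exact p when both inputs are tie-free and short, tie-corrected normal
    approximation otherwise (scipy's default switching rule, which is the
    convention the reference tables follow).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("tau undefined for all-constant input")
    res = scipy.stats.kendalltau(x, y, variant="b", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# the property-test grid
# ---------------------------------------------------------------------------

@dataclass
class PropertyTestResult:
    """One (model, method, mode, role, property) statistical test."""

    model: str
    xai_method: str
    mode: str
    role: str
    property: str
    kind: str  # 'categorical' | 'numerical'
    statistic: float = np.nan  # U or tau
    p_value: float = np.nan
    correlation: float = np.nan  # signed tau for numerical tests
    evaluable: bool = True

    def passed(self, alpha: float = ALPHA_DEFAULT) -> bool:
        if alpha >= 1.0:  # degenerate threshold: every evaluable test passes
            return bool(self.evaluable)
        return bool(self.evaluable and self.p_value < alpha)


def _categorical_groups(score_sets: list[ResidueScoreSet], role: str, prop: str):
    """Pooled per-residue score split for one categorical property."""
    ga, gb = [], []
    for s in score_sets:
        scores = s.target_scores if role == "target" else s.source_scores
        for pos, (letter, v) in enumerate(zip(s.sequence, scores)):
            if prop == "interactivity":
                if s.interaction_labels is None:
                    continue
                (ga if s.interaction_labels[pos] == 1 else gb).append(v)
            elif prop == "aromaticity":
                (ga if letter in AROMATIC else gb).append(v)
            elif prop == "acidity_basicity":
                if letter in ACIDIC:
                    ga.append(v)
                elif letter in BASIC:
                    gb.append(v)
    return np.array(ga), np.array(gb)


def run_property_tests(matrices: dict, property_table: pd.DataFrame,
                       transform: str = "signed") -> list[PropertyTestResult]:
    """Run the full 7-property x 2-role test grid for every matrix set.

    ``matrices`` maps (model, xai_method, mode) to a list of
    (ProteinRecord, matrix) pairs.  Interactivity tests require records
    with interaction labels; an empty category yields a result marked
    not-evaluable rather than a silent pass.
    """
    results: list[PropertyTestResult] = []
    prop_cols = {p: property_table[p].to_numpy(dtype=np.float64)
                 for p in NUMERICAL_PROPERTIES}
    for (model, method, mode), pairs in sorted(matrices.items()):
        score_sets = [
            residue_scores(X, rec.sequence, transform, rec.name, rec.interaction_labels)
            for rec, X in pairs
        ]
        for role in ("target", "source"):
            for prop in CATEGORICAL_PROPERTIES:
                ga, gb = _categorical_groups(score_sets, role, prop)
                res = PropertyTestResult(model, method, mode, role, prop, "categorical")
                if ga.size == 0 or gb.size == 0:
                    res.evaluable = False
                else:
                    res.statistic, res.p_value = mann_whitney_u(ga, gb)
                results.append(res)
            vec = amino_acid_mean_scores(score_sets, role)
            present = ~np.isnan(vec)
            for prop in NUMERICAL_PROPERTIES:
                res = PropertyTestResult(model, method, mode, role, prop, "numerical")
                if present.sum() < 3:
                    res.evaluable = False
                else:
                    try:
                        tau, p = kendall_tau(vec[present], prop_cols[prop][present])
                    except ValueError:  # degenerate (constant) score vector
                        res.evaluable = False
                    else:
                        res.statistic, res.p_value, res.correlation = tau, p, tau
                results.append(res)
    return results


# ---------------------------------------------------------------------------
# summarization
# ---------------------------------------------------------------------------

def results_frame(results) -> pd.DataFrame:
    """Normalize results (list of PropertyTestResult, a ReportedPValueTable,
    or an already-tidy DataFrame) to one tidy frame."""
    if isinstance(results, ReportedPValueTable):
        return results.combined()
    if isinstance(results, pd.DataFrame):
        return results
    rows = [
        {"model": r.model, "xai_method": r.xai_method, "mode": r.mode,
         "role": r.role, "property": r.property, "kind": r.kind,
         "tau": r.correlation, "p_value": r.p_value,
         "evaluable": r.evaluable}
        for r in results
    ]
    return pd.DataFrame(rows)


def _passes(frame: pd.DataFrame, alpha: float) -> pd.Series:
    # alpha >= 1 is the degenerate always-reject threshold
    ok = frame["p_value"] < alpha if alpha < 1.0 else frame["p_value"] <= 1.0
    if "evaluable" in frame:
        ok &= frame["evaluable"].fillna(True).astype(bool)
    return ok


@dataclass
class PassCountSummary:
    """Pass counts over the test grid, in the layout of the reference tables."""

    by_method_model: pd.DataFrame  # rows: method; cols: (model, kind) counts
    by_method_testtype: pd.DataFrame
    by_model_testtype: pd.DataFrame
    grand_total: int
    categorical_total: int
    numerical_total: int
    categorical_pct: int  # integer percent of categorical tests passed
    numerical_pct: int
    overall_pct: int


def summarize_pass_counts(results, alpha: float = ALPHA_DEFAULT) -> PassCountSummary:
    """Count passed tests by method x model, method x test type and
    model x test type."""
    frame = results_frame(results).copy()
    key = ["model", "xai_method", "mode", "role", "property"]
    if frame.duplicated(key).any():
        raise ValueError("duplicate result keys in test grid")
    frame["pass"] = _passes(frame, alpha)

    methods = list(dict.fromkeys(frame["xai_method"]))
    models = list(dict.fromkeys(frame["model"]))

    mm = pd.DataFrame(index=methods)
    for model in models + ["all"]:
        sub = frame if model == "all" else frame[frame["model"] == model]
        for kind in ("categorical", "numerical", "total"):
            s = sub if kind == "total" else sub[sub["kind"] == kind]
            mm[(model, kind)] = s.groupby("xai_method")["pass"].sum().reindex(methods).fillna(0).astype(int)
    mm.columns = pd.MultiIndex.from_tuples(mm.columns)

    mt = pd.DataFrame(index=methods)
    for tt in TEST_TYPES:
        col = "role" if tt in ("target", "source") else "mode"
        sub = frame[frame[col] == tt]
        mt[tt] = sub.groupby("xai_method")["pass"].sum().reindex(methods).fillna(0).astype(int)

    et = pd.DataFrame(index=list(TEST_TYPES))
    for model in models + ["all"]:
        msub = frame if model == "all" else frame[frame["model"] == model]
        for kind in ("categorical", "numerical", "total"):
            s = msub if kind == "total" else msub[msub["kind"] == kind]
            vals = []
            for tt in TEST_TYPES:
                col = "role" if tt in ("target", "source") else "mode"
                vals.append(int(s[s[col] == tt]["pass"].sum()))
            et[(model, kind)] = vals
    et.columns = pd.MultiIndex.from_tuples(et.columns)

    cat = frame[frame["kind"] == "categorical"]
    num = frame[frame["kind"] == "numerical"]
    return PassCountSummary(
        by_method_model=mm,
        by_method_testtype=mt,
        by_model_testtype=et,
        grand_total=int(frame["pass"].sum()),
        categorical_total=int(cat["pass"].sum()),
        numerical_total=int(num["pass"].sum()),
        categorical_pct=round_half_away(100 * cat["pass"].mean()) if len(cat) else 0,
        numerical_pct=round_half_away(100 * num["pass"].mean()) if len(num) else 0,
        overall_pct=round_half_away(100 * frame["pass"].mean()),
    )


def crosstab_embedding_vs_prediction(results, alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """Cross-tabulate embedding-mode vs prediction-mode pass status.

    For every (model, method, property, role) both mode results must be
    present; returns counts of pass|pass, pass|fail, fail|pass, fail|fail
    per (model, kind) plus marginals over kind and overall.
    """
    frame = results_frame(results).copy()
    frame["pass"] = _passes(frame, alpha)
    key = ["model", "xai_method", "role", "property", "kind"]
    piv = frame.pivot_table(index=key, columns="mode", values="pass", aggfunc="first")
    if piv.isna().any().any() or set(piv.columns) != {"embedding", "prediction"}:
        raise ValueError("missing mode partner in embedding/prediction cross-tab")
    piv = piv.reset_index()
    cells = ("pass|pass", "pass|fail", "fail|pass", "fail|fail")

    def label(row):
        return ("pass" if row["embedding"] else "fail") + "|" + \
               ("pass" if row["prediction"] else "fail")

    piv["cell"] = piv.apply(label, axis=1)
    out = {}
    models = list(dict.fromkeys(frame["model"])) + ["all"]
    for model in models:
        sub = piv if model == "all" else piv[piv["model"] == model]
        for kind in ("categorical", "numerical", "total"):
            s = sub if kind == "total" else sub[sub["kind"] == kind]
            counts = s["cell"].value_counts()
            col = [int(counts.get(c, 0)) for c in cells]
            col.append(len(s))
            out[(model, kind)] = col
    return pd.DataFrame(out, index=list(cells) + ["total"])


@dataclass
class ExclusivitySummary:
    """Which tests are passed by exactly one model.

    Two denominators are reported because both occur in practice: the full
    test grid and the set of tests passed by at least one model.
    """

    kind: str
    grid_total: int
    at_least_one: int
    exactly_one: int
    only_counts: dict[str, int]
    pct_of_passed: int  # exactly-one / at-least-one, integer percent
    pct_of_grid: int  # exactly-one / grid, integer percent


def exclusive_pass_analysis(results, alpha: float = ALPHA_DEFAULT) -> dict[str, ExclusivitySummary]:
    """Per test (method x property x role x mode): which models pass.

    Returns summaries keyed 'categorical', 'numerical' and 'all'.
    """
    frame = results_frame(results).copy()
    frame["pass"] = _passes(frame, alpha)
    models = list(dict.fromkeys(frame["model"]))
    key = ["xai_method", "mode", "role", "property", "kind"]
    grid = frame.groupby(key)["model"].nunique()
    if (grid != len(models)).any():
        raise ValueError("test grid incomplete: not every model covers every test")
    passed = frame[frame["pass"]].groupby(key)["model"].agg(frozenset)

    out = {}
    for kind in ("categorical", "numerical", "all"):
        keys = [k for k in grid.index if kind in ("all", k[-1])]
        sets = [passed.get(k, frozenset()) for k in keys]
        exactly1 = sum(1 for s in sets if len(s) == 1)
        atleast1 = sum(1 for s in sets if len(s) >= 1)
        only = {m: sum(1 for s in sets if s == frozenset({m})) for m in models}
        out[kind] = ExclusivitySummary(
            kind=kind,
            grid_total=len(keys),
            at_least_one=atleast1,
            exactly_one=exactly1,
            only_counts=only,
            pct_of_passed=round_half_away(100 * exactly1 / atleast1) if atleast1 else 0,
            pct_of_grid=round_half_away(100 * exactly1 / len(keys)) if keys else 0,
        )
    return out


# ---------------------------------------------------------------------------
# distance profiles
# ---------------------------------------------------------------------------

@dataclass
class DistanceProfile:
    """Mean impact score against linear sequence separation d = 0..max_distance."""

    distances: np.ndarray
    mean_score: np.ndarray  # NaN where no residue pair attains the distance
    pair_counts: np.ndarray
    transform: str


def distance_profile(matrices, max_distance: int = 20,
                     transform: str = "absolute") -> DistanceProfile:
    """Pool |X[i, j]| (or signed X) over all ordered pairs with |i-j| = d."""
    sums = np.zeros(max_distance + 1)
    counts = np.zeros(max_distance + 1, dtype=np.int64)
    for X in matrices:
        if isinstance(X, ResidueImpactMatrix):
            X = X.X
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("matrices must be square")
        vals = np.abs(X) if transform == "absolute" else X
        n = X.shape[0]
        idx = np.arange(n)
        dist = np.abs(idx[:, None] - idx[None, :])
        for d in range(min(max_distance, n - 1) + 1):
            mask = dist == d
            sums[d] += vals[mask].sum()
            counts[d] += int(mask.sum())
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DistanceProfile(np.arange(max_distance + 1), mean, counts, transform)


# ---------------------------------------------------------------------------
# structured-vs-random separability
# ---------------------------------------------------------------------------

def _featurize(matrix: np.ndarray, grid: int) -> np.ndarray:
    """Fixed-size feature vector: bilinear resampling to grid x grid, flattened."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.shape == (grid, grid):
        return m.reshape(-1)
    return resize(m, (grid, grid), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True).reshape(-1)


def random_separability_check(real_matrices, seed: int,
                              train_fraction: float = 0.8,
                              grid: int = 32) -> float:
    """Held-out accuracy of an RBF-kernel SVM at telling structured
    attribution matrices from moment-matched Gaussian random matrices.

    One random matrix (same shape, same mean and standard deviation) is
    generated per real matrix; features are bilinear 32 x 32 resamplings;
    the split is seeded and stratified.
    """
    mats = [m.X if isinstance(m, ResidueImpactMatrix) else np.asarray(m, dtype=np.float64)
            for m in real_matrices]
    if len(mats) < 20:
        raise ValueError("need at least 20 real matrices")
    feats, labels = [], []
    for i, m in enumerate(mats):
        feats.append(_featurize(m, grid))
        labels.append(1)
        rnd = generate_random_matrix(m.shape[0], m.shape[1],
                                     float(m.mean()), float(m.std()) or 1e-12,
                                     seed=(seed * 100003 + i) % (2 ** 31))
        feats.append(_featurize(rnd, grid))
        labels.append(0)
    Xf = np.vstack(feats)
    y = np.array(labels)
    if not np.isfinite(Xf).all() or Xf.std() == 0:
        raise ValueError("degenerate features")
    Xtr, Xte, ytr, yte = train_test_split(
        Xf, y, train_size=train_fraction, stratify=y, random_state=seed % (2 ** 31)
    )
    scaler = StandardScaler().fit(Xtr)
    clf = SVC(kernel="rbf", gamma="scale", C=1.0)
    clf.fit(scaler.transform(Xtr), ytr)
    return float(clf.score(scaler.transform(Xte), yte))
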