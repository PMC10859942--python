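"""Compress a delta matrix into composite influence scores.

The five delta-NP columns are standardized and decomposed by
correlation-matrix PCA (eigendecomposition of the Pearson correlation
matrix).  Correlation PCA -- rather than covariance PCA -- is required for
two reasons: Kaiser's eigenvalue >= 1 retention rule is only meaningful when
every variable contributes unit variance, and the delta columns live on
wildly different scales (dDC counts edges; dGCC lives in [0, 1]).

Components are retained while they satisfy Kaiser's rule (eigenvalue >= 1)
OR explain at least 10% of the variance; at least the first component is
always kept.  The composite influence score of an element is the
eigenvalue-weighted sum of its retained component scores, with component
signs anchored so that the loading on dDC is non-negative -- higher
composite score therefore always means "removal costs the network more".

Zero-variance columns (e.g. dDC under LOEO in degree-sum mode, where every
edge removal subtracts exactly 2) are dropped with a warning before the
decomposition, so degenerate-but-legitimate inputs still run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from looa.errors import DegenerateDataError, GraphSizeError, ParameterError

logger = logging.getLogger(__name__)

#: Hub-class degree bins: (class name, minimum degree, maximum degree).
HUB_BINS = (
    ("mega", 100, None),
    ("major", 50, 99),
    ("midi", 10, 49),
    ("mini", 6, 9),
    ("sub", 0, 5),
)

# Relative tolerance below which a column is treated as constant.
_VARIANCE_EPS = 1e-12


@dataclass(frozen=True)
class PcaModel:
    """Correlation-matrix PCA of a standardized delta matrix.

    Attributes
    ----------
    eigenvalues : ndarray
        Variances of the standardized data along each component, descending;
        they sum to the number of retained columns.
    variance_pct : ndarray
        ``eigenvalue / n_retained_columns * 100`` per component.
    loadings : DataFrame, variables x components
        Variable coordinates: eigenvector entries scaled by sqrt(eigenvalue).
    scores : DataFrame, elements x components
        Projections of the standardized rows onto the components.
    components : DataFrame, variables x components
        The unit-norm eigenvectors themselves.
    retained_columns, dropped_columns : lists
        Which delta columns entered the PCA and which were constant.
    """

    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    components: pd.DataFrame
    retained_columns: list[str] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class ComponentSelection:
    """Retained components (0-based indices) and the rule(s) each one hit."""

    selected: tuple[int, ...]
    rule_hits: dict[int, tuple[str, ...]]


def correlation_matrix(delta: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between the delta columns.

    Zero-variance columns have no defined correlation; their entries are NaN
    (missing), never silently 0.

    Raises
    ------
    GraphSizeError
        If the matrix has fewer than 3 rows.
    """
    if len(delta) < 3:
        raise GraphSizeError("correlation matrix requires at least 3 elements")
    return delta.corr(method="pearson")


def _constant_columns(delta: pd.DataFrame) -> list[str]:
    stds = delta.std(ddof=1)
    scale = delta.abs().mean().clip(lower=1.0)
    return [c for c in delta.columns if not stds[c] > _VARIANCE_EPS * scale[c]]


def fit_pca(delta: pd.DataFrame) -> PcaModel:
    """Fit a correlation-matrix PCA to a delta matrix.

    Constant columns are dropped first (warned, recorded on the model); the
    rest are centered, scaled to unit variance (ddof=1), and the correlation
    matrix is eigendecomposed.  Component signs are fixed so that the loading
    on dDC is non-negative (falling back to the largest-magnitude loading if
    dDC itself was dropped), which makes score orientation deterministic.

    Raises
    ------
    GraphSizeError
        If the matrix has fewer than 3 rows.
    DegenerateDataError
        If fewer than 2 columns have nonzero variance; the message names the
        constant columns.
    """
    if len(delta) < 3:
        raise GraphSizeError("PCA requires at least 3 elements")
    dropped = _constant_columns(delta)
    retained = [c for c in delta.columns if c not in dropped]
    if dropped:
        logger.warning("dropping zero-variance column(s): %s", ", ".join(dropped))
    if len(retained) < 2:
        raise DegenerateDataError(
            f"correlation PCA needs at least 2 non-constant columns; "
            f"constant: {', '.join(dropped) or 'none'}"
        )

    data = delta[retained].to_numpy(dtype=float)
    z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
    corr = (z.T @ z) / (len(z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    # Anchor each component's sign to a delta that is non-negative by
    # construction: dDC first, else dCC (harmonic closeness can only shrink
    # under deletion), else the largest-magnitude loading.  Anchoring to a
    # sign-guaranteed delta keeps "higher score = removal costs the network
    # more" true even when degree is constant (LOEO in sum mode).
    anchor = next((retained.index(c) for c in ("dDC", "dCC") if c in retained), None)
    for k in range(eigvec.shape[1]):
        ref = eigvec[anchor, k] if anchor is not None else 0.0
        if ref == 0.0:
            ref = eigvec[np.argmax(np.abs(eigvec[:, k])), k]
        if ref < 0:
            eigvec[:, k] *= -1

    comp_names = [f"PC{k + 1}" for k in range(len(retained))]
    components = pd.DataFrame(eigvec, index=retained, columns=comp_names)
    loadings = components * np.sqrt(eigval)
    scores = pd.DataFrame(z @ eigvec, index=delta.index, columns=comp_names)
    return PcaModel(
        eigenvalues=eigval,
        variance_pct=eigval / len(retained) * 100.0,
        loadings=loadings,
        scores=scores,
        components=components,
        retained_columns=retained,
        dropped_columns=dropped,
    )


def select_components(
    model: PcaModel, kaiser_cut: float = 1.0, var_cut: float = 10.0
) -> ComponentSelection:
    """Retain leading components by Kaiser's rule OR the variance rule.

    A component is kept if its eigenvalue is >= ``kaiser_cut`` or it explains
    at least ``var_cut`` percent of the variance; either threshold suffices.
    Because eigenvalues are sorted, the kept set is a prefix of the component
    order.  If no component passes, the first is kept anyway -- an empty
    selection would make the ranking silently meaningless.
    """
    if kaiser_cut <= 0 or var_cut <= 0:
        raise ParameterError("selection thresholds must be positive")
    selected: list[int] = []
    hits: dict[int, tuple[str, ...]] = {}
    for k in range(model.n_components):
        rules = []
        if model.eigenvalues[k] >= kaiser_cut:
            rules.append("eigenvalue")
        if model.variance_pct[k] >= var_cut:
            rules.append("variance")
        if not rules:
            break
        selected.append(k)
        hits[k] = tuple(rules)
    if not selected:
        selected = [0]
        hits[0] = ("fallback",)
    return ComponentSelection(selected=tuple(selected), rule_hits=hits)


def cos2(model: PcaModel) -> pd.DataFrame:
    """Squared cosines: quality of representation of each variable.

    Entry (variable, component) is the squared variable coordinate; each
    variable's row sums to 1 across all components (the diagonal of the
    correlation matrix).
    """
    return model.loadings**2


def composite_scores(model: PcaModel, selection: ComponentSelection) -> pd.DataFrame:
    """Eigenvalue-weighted sum of the selected component scores per element.

    ``score(i) = sum_k w_k * score_k(i)`` with ``w_k`` the selected
    eigenvalues normalized to sum 1; with a single selected component this
    is exactly that component's scores.  Returns a one-column
    ``composite_score`` frame indexed like the delta matrix.
    """
    idx = list(selection.selected)
    weights = model.eigenvalues[idx]
    weights = weights / weights.sum()
    composite = model.scores.iloc[:, idx].to_numpy() @ weights
    return pd.DataFrame({"composite_score": composite}, index=model.scores.index)


def rank_elements(table: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Sort by descending composite score and assign 1-based ranks.

    Exact score ties are broken by lexicographic element identifier, then
    the table is truncated to ``top_n`` rows (if given).

    Raises
    ------
    ParameterError
        If ``top_n`` is given and < 1.
    """
    if top_n is not None and top_n < 1:
        raise ParameterError(f"top_n must be >= 1, got {top_n}")
    # mergesort is stable, so pre-sorting by id yields the lexicographic tie-break
    ordered = table.sort_index(kind="mergesort").sort_values(
        by="composite_score", ascending=False, kind="mergesort"
    ).copy()
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    if top_n is not None:
        ordered = ordered.head(top_n)
    return ordered


def classify_hubs(graph: nx.Graph) -> dict:
    """Assign each protein a hub class from its interaction count.

    Mega-hubs have >= 100 interactions, major hubs 50-99, midi-hubs 10-49,
    mini-hubs 6-9; anything with 5 or fewer is "sub".
    """
    if graph.number_of_nodes() == 0:
        raise GraphSizeError("graph has no vertices")
    classes = {}
    for vertex, degree in graph.degree():
        for name, lo, hi in HUB_BINS:
            if degree >= lo and (hi is None or degree <= hi):
                classes[vertex] = name
                break
    return classes


def score_influence(
    delta: pd.DataFrame,
    graph: nx.Graph | None = None,
    kaiser_cut: float = 1.0,
    var_cut: float = 10.0,
    top_n: int | None = None,
) -> "InfluenceResult":
    """Full scoring pipeline: PCA, selection, composite scores, ranking.

    Degenerate delta matrices degrade gracefully instead of failing: with
    exactly one non-constant column the standardized column itself is the
    composite score (a one-variable PCA), and with none -- e.g. the LOVO of
    a clique, where every removal is equivalent by symmetry -- all elements
    tie at score 0 and the ranking falls back to identifier order.

    If ``graph`` is given, row labels found among its vertices get a
    ``hub_class`` column (LOVO rankings).
    """
    model: PcaModel | None = None
    selection: ComponentSelection | None = None
    try:
        model = fit_pca(delta)
        selection = select_components(model, kaiser_cut=kaiser_cut, var_cut=var_cut)
        scores = composite_scores(model, selection)
    except DegenerateDataError:
        usable = [c for c in delta.columns if c not in _constant_columns(delta)]
        if usable:
            col = delta[usable[0]].to_numpy(dtype=float)
            z = (col - col.mean()) / col.std(ddof=1)
            logger.warning(
                "only one non-constant column (%s); composite score is its z-score",
                usable[0],
            )
            scores = pd.DataFrame({"composite_score": z}, index=delta.index)
        else:
            logger.warning("all delta columns constant; every element ties at 0")
            scores = pd.DataFrame({"composite_score": 0.0}, index=delta.index)

    ranking = rank_elements(scores, top_n=top_n)
    if graph is not None:
        hub = classify_hubs(graph)
        labels = {str(v): c for v, c in hub.items()}
        if all(e in labels for e in ranking.index):
            ranking = ranking.copy()
            ranking["hub_class"] = [labels[e] for e in ranking.index]
    return InfluenceResult(
        delta=delta, model=model, selection=selection, scores=scores, ranking=ranking
    )


@dataclass(frozen=True)
class InfluenceResult:
    """Everything the scoring pipeline produced for one analysis."""

    delta: pd.DataFrame
    model: PcaModel | None
    selection: ComponentSelection | None
    scores: pd.DataFrame
    ranking: pd.DataFrame
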