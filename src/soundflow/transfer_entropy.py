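"""Plug-in Shannon and Renyi transfer entropy between symbolic time series.

Transfer entropy (TE) measures the directed, model-free information flow from
a source series X to a target series Y as the Kullback-Leibler departure of
the target's transition probabilities from a generalized Markov condition
p(y_{t+1} | y_t^n, x_t^m) = p(y_{t+1} | y_t^n).  The Shannon form is

    STE(X -> Y) = sum p(y_{t+1}, y_t^n, x_t^m)
                      * log2 [ p(y_{t+1} | y_t^n, x_t^m) / p(y_{t+1} | y_t^n) ],

with STE(X -> X) = 0.  The Renyi form weights the conditioning contexts by the
escort distribution phi_q(j) = p(j)^q / sum_j p(j)^q:

    RTE(X -> Y) = 1/(1-q) * log2 [ sum phi_q(y^n)      p(y_{t+1}|y^n)^q
                                 / sum phi_q(y^n, x^m) p(y_{t+1}|y^n, x^m)^q ],

which converges to STE as q -> 1; q < 1 emphasizes rare (tail) transitions,
q > 1 frequent ones.  All values are in bits (base-2 logarithms).

Estimation is plug-in: empirical transition counts over discretized (symbolic)
series, with transitions never crossing contiguity-block boundaries (e.g.
duty-cycle gaps or period splits).  No bias correction is applied; a
shuffle-based null (:func:`shuffle_null`) is available as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DiscretizationScheme",
    "SymbolicSeries",
    "TEParams",
    "JointDistribution",
    "TEEstimate",
    "discretize",
    "shannon_entropy",
    "renyi_entropy",
    "shannon_te",
    "renyi_te",
    "transfer_entropy_from_joint",
    "shuffle_null",
    "te_matrix",
]


# ---------------------------------------------------------------------------
# contiguity blocks
# ---------------------------------------------------------------------------

def blocks_from_mask(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean mask."""
    valid = np.asarray(valid, bool)
    if valid.size == 0:
        return []
    edges = np.flatnonzero(np.diff(valid.astype(np.int8)))
    bounds = np.concatenate([[0], edges + 1, [valid.size]])
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if valid[a]:
            out.append((int(a), int(b)))
    return out


def intersect_blocks(
    a: list[tuple[int, int]], b: list[tuple[int, int]], n: int
) -> list[tuple[int, int]]:
    """Pairwise interval intersection; boundaries from either side survive
    (adjacent blocks are never merged)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((int(s), int(e)))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizationScheme:
    """Per-series quantile discretization.

    ``boundaries`` are percentile levels in (0, 100); the default (5, 95)
    yields a 3-letter alphabet separating the lower tail, bulk and upper tail
    of each series.  Values falling exactly on an edge go to the lower bin.
    ``on_degenerate`` controls series whose quantile edges collapse: raise,
    or merge duplicate edges into a coarser alphabet.
    """

    boundaries: tuple = (5.0, 95.0)
    on_degenerate: str = "raise"  # or "merge"

    def __post_init__(self):
        b = tuple(float(v) for v in self.boundaries)
        if len(b) < 1 or any(not (0.0 < v < 100.0) for v in b):
            raise ValueError("boundaries must lie strictly inside (0, 100)")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")
        if self.on_degenerate not in ("raise", "merge"):
            raise ValueError("on_degenerate must be 'raise' or 'merge'")
        object.__setattr__(self, "boundaries", b)


@dataclass
class SymbolicSeries:
    """Discretized series: integer symbols plus contiguity blocks."""

    symbols: np.ndarray
    alphabet_size: int
    blocks: list = field(default_factory=list)
    site_id: object = None
    index_name: str | None = None
    period_label: str = "all"
    bin_edges: np.ndarray | None = None

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols)
        if not self.blocks:
            self.blocks = [(0, len(self.symbols))]
        valid = np.concatenate(
            [self.symbols[s:e] for s, e in self.blocks]
        ) if self.blocks else np.array([], int)
        if valid.size and (valid.min() < 0 or valid.max() >= self.alphabet_size):
            raise ValueError("symbols outside [0, alphabet_size)")
        last = 0
        for s, e in self.blocks:
            if s < last or e <= s or e > len(self.symbols):
                raise ValueError("blocks must be non-overlapping and ordered")
            last = e

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class TEParams:
    """Estimator configuration: Markov orders, estimator family, Renyi q."""

    m: int = 1
    n: int = 1
    estimator: str = "shannon"
    q: float | None = None

    def __post_init__(self):
        if self.m < 1 or self.n < 1:
            raise ValueError("Markov orders m, n must be >= 1")
        if self.estimator not in ("shannon", "renyi"):
            raise ValueError("estimator must be 'shannon' or 'renyi'")
        if self.estimator == "renyi":
            if self.q is None or self.q <= 0 or self.q == 1:
                raise ValueError("renyi estimator needs q > 0, q != 1")


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize(
    values,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    blocks: list | None = None,
    **meta,
) -> SymbolicSeries:
    """Quantile-discretize a real series into integer symbols.

    Quantile edges (linear interpolation) are computed on the series' own
    finite values; a value equal to an edge is assigned to the lower bin, so
    the symbol sequence is invariant under strictly increasing transforms of
    the values.  Non-finite values split contiguity blocks.
    """
    values = np.asarray(values, float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D series")
    finite = np.isfinite(values)
    fin_vals = values[finite]
    if fin_vals.size < 20:
        raise ValueError("need at least 20 finite values to discretize")
    edges = np.percentile(fin_vals, scheme.boundaries)
    n_bins = len(edges) + 1
    distinct = np.unique(fin_vals)
    degenerate = (len(np.unique(edges)) < len(edges)) or (distinct.size < n_bins)
    if degenerate:
        if scheme.on_degenerate == "raise":
            raise ValueError(
                f"series supports fewer than {n_bins} bins "
                "(too few distinct values); use fewer boundaries or "
                "on_degenerate='merge'"
            )
        edges = np.unique(edges)
        n_bins = len(edges) + 1
    symbols = np.searchsorted(edges, values, side="left")
    symbols[~finite] = -1
    if blocks is None:
        blocks = [(0, len(values))]
    blocks = intersect_blocks(blocks, blocks_from_mask(finite), len(values))
    return SymbolicSeries(
        symbols=symbols,
        alphabet_size=n_bins,
        blocks=blocks,
        bin_edges=edges,
        **meta,
    )


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

def _check_pmf(p) -> np.ndarray:
    p = np.asarray(p, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a 1-D probability vector")
    if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("probabilities must be non-negative and sum to 1")
    return p


def shannon_entropy(p) -> float:
    """Shannon entropy -sum p log2 p in bits, with 0*log0 = 0."""
    p = _check_pmf(p)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def renyi_entropy(p, q: float) -> float:
    """Renyi entropy (1/(1-q)) log2 sum p^q in bits (q > 0, q != 1)."""
    if q <= 0:
        raise ValueError("q must be positive")
    if q == 1:
        raise ValueError("q = 1 is the Shannon limit; use shannon_entropy")
    p = _check_pmf(p)
    nz = p[p > 0]
    return float(np.log2((nz**q).sum()) / (1.0 - q))


# ---------------------------------------------------------------------------
# joint transition distribution
# ---------------------------------------------------------------------------

@dataclass
class JointDistribution:
    """Weights over (y_{t+1}, y_t^n, x_t^m) transition tuples.

    ``weights`` maps tuples ``(y_next, y_hist, x_hist)`` — with histories as
    tuples ordered most-recent-first — to counts (or probabilities, when built
    from an exact process model).  Marginals are derived on demand and are
    consistent with the joint by construction.
    """

    weights: dict
    alphabet_size: int
    m: int
    n: int
    n_transitions: float = 0.0

    @classmethod
    def from_symbols(
        cls, x: SymbolicSeries, y: SymbolicSeries, m: int = 1, n: int = 1
    ) -> "JointDistribution":
        if len(x) != len(y):
            raise ValueError("source and target series must have equal length")
        if x.alphabet_size != y.alphabet_size:
            # mixed alphabets are fine for the estimator; track the max
            pass
        blocks = intersect_blocks(x.blocks, y.blocks, len(x))
        k = max(m, n)
        xs, ys = x.symbols, y.symbols
        weights: dict = {}
        total = 0
        if m == 1 and n == 1:
            # vectorized counting: encode each (y_next, y_t, x_t) triple
            alpha = int(max(x.alphabet_size, y.alphabet_size))
            chunks = [
                (ys[s + 1 : e], ys[s : e - 1], xs[s : e - 1])
                for s, e in blocks
                if e - s > 1
            ]
            if chunks:
                y_next = np.concatenate([c[0] for c in chunks]).astype(np.int64)
                y_hist = np.concatenate([c[1] for c in chunks]).astype(np.int64)
                x_hist = np.concatenate([c[2] for c in chunks]).astype(np.int64)
                codes = (y_next * alpha + y_hist) * alpha + x_hist
                uniq, counts = np.unique(codes, return_counts=True)
                for code, cnt in zip(uniq.tolist(), counts.tolist()):
                    xh = code % alpha
                    yh = (code // alpha) % alpha
                    yn = code // (alpha * alpha)
                    weights[(yn, (yh,), (xh,))] = cnt
                total = int(counts.sum())
            return cls(
                weights=weights,
                alphabet_size=alpha,
                m=m,
                n=n,
                n_transitions=total,
            )
        for s, e in blocks:
            length = e - s
            if length <= k:
                continue
            for t in range(s + k - 1, e - 1):
                y_hist = tuple(int(ys[t - i]) for i in range(n))
                x_hist = tuple(int(xs[t - i]) for i in range(m))
                key = (int(ys[t + 1]), y_hist, x_hist)
                weights[key] = weights.get(key, 0) + 1
                total += 1
        return cls(
            weights=weights,
            alphabet_size=max(x.alphabet_size, y.alphabet_size),
            m=m,
            n=n,
            n_transitions=total,
        )

    @classmethod
    def from_probabilities(
        cls, probs: dict, alphabet_size: int, m: int = 1, n: int = 1
    ) -> "JointDistribution":
        """Exact joint over transition tuples (probabilities sum to 1)."""
        total = float(sum(probs.values()))
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("probabilities must sum to 1")
        return cls(
            weights=dict(probs),
            alphabet_size=alphabet_size,
            m=m,
            n=n,
            n_transitions=total,
        )

    # marginal accumulators -------------------------------------------------
    def marginals(self):
        c_yx: dict = {}   # (y_hist, x_hist)
        c_yy: dict = {}   # (y_next, y_hist)
        c_y: dict = {}    # y_hist
        for (y_next, y_hist, x_hist), w in self.weights.items():
            c_yx[(y_hist, x_hist)] = c_yx.get((y_hist, x_hist), 0) + w
            c_yy[(y_next, y_hist)] = c_yy.get((y_next, y_hist), 0) + w
            c_y[y_hist] = c_y.get(y_hist, 0) + w
        return c_yx, c_yy, c_y


# ---------------------------------------------------------------------------
# TE estimates
# ---------------------------------------------------------------------------

@dataclass
class TEEstimate:
    """A single directed TE value in bits plus its provenance."""

    value: float
    direction: tuple = (None, None)
    params: TEParams = TEParams()
    n_transitions: float = 0.0
    null_summary: dict | None = None


def transfer_entropy_from_joint(
    joint: JointDistribution, params: TEParams = TEParams()
) -> float:
    """Evaluate STE or RTE (bits) from a joint transition distribution.

    Degenerate (zero-weight) contexts contribute nothing; escort
    normalization runs over observed contexts only.
    """
    total = joint.n_transitions
    if total <= 0:
        raise ValueError("joint distribution has no transitions")
    c_yx, c_yy, c_y = joint.marginals()
    if params.estimator == "shannon":
        acc = 0.0
        for (y_next, y_hist, x_hist), w in joint.weights.items():
            # ratio of conditionals as a ratio of count products: exact 1.0
            # (hence exact log 0) whenever source duplicates target
            num = w * c_y[y_hist]
            den = c_yx[(y_hist, x_hist)] * c_yy[(y_next, y_hist)]
            acc += (w / total) * np.log2(num / den)
        return float(acc)
    q = params.q
    z_y = sum(v**q for v in c_y.values())
    z_yx = sum(v**q for v in c_yx.values())
    numer = 0.0
    for (y_next, y_hist), w in c_yy.items():
        numer += (c_y[y_hist] ** q / z_y) * (w / c_y[y_hist]) ** q
    denom = 0.0
    for (y_next, y_hist, x_hist), w in joint.weights.items():
        cyx = c_yx[(y_hist, x_hist)]
        denom += (cyx**q / z_yx) * (w / cyx) ** q
    return float(np.log2(numer / denom) / (1.0 - q))


def _estimate(
    x: SymbolicSeries, y: SymbolicSeries, params: TEParams
) -> TEEstimate:
    joint = JointDistribution.from_symbols(x, y, m=params.m, n=params.n)
    min_needed = joint.alphabet_size ** (params.m + params.n + 1)
    if joint.n_transitions < min_needed:
        warnings.warn(
            f"only {joint.n_transitions} transitions for "
            f"{min_needed} possible states; TE estimate may be unstable",
            stacklevel=3,
        )
    value = transfer_entropy_from_joint(joint, params)
    return TEEstimate(
        value=value,
        direction=(x.site_id, y.site_id),
        params=params,
        n_transitions=joint.n_transitions,
    )


def shannon_te(
    x: SymbolicSeries, y: SymbolicSeries, params: TEParams | None = None
) -> TEEstimate:
    """Plug-in Shannon transfer entropy X -> Y in bits (never negative)."""
    params = params or TEParams()
    if params.estimator != "shannon":
        params = replace(params, estimator="shannon", q=None)
    return _estimate(x, y, params)


def renyi_te(
    x: SymbolicSeries, y: SymbolicSeries, q: float, m: int = 1, n: int = 1
) -> TEEstimate:
    """Plug-in Renyi transfer entropy X -> Y in bits (may be negative)."""
    return _estimate(x, y, TEParams(m=m, n=n, estimator="renyi", q=q))


# ---------------------------------------------------------------------------
# shuffle null
# ---------------------------------------------------------------------------

def shuffle_null(
    x: SymbolicSeries,
    y: SymbolicSeries,
    params: TEParams | None = None,
    reps: int = 100,
    seed: int | None = None,
) -> dict:
    """Block-respecting permutation null for TE(X -> Y).

    The source symbols are independently permuted within each contiguity
    block, destroying the lagged X-Y relation while preserving the marginal
    symbol distribution and the block layout.  Returns the null mean and sd,
    and the percentile of the observed value within the null sample.
    """
    params = params or TEParams()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if reps < 19:
        warnings.warn("fewer than 19 shuffles gives a coarse null", stacklevel=2)
    rng = np.random.default_rng(seed)
    observed = _estimate(x, y, params).value
    null_vals = np.empty(reps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(reps):
            shuffled = x.symbols.copy()
            for s, e in x.blocks:
                shuffled[s:e] = rng.permutation(shuffled[s:e])
            xs = SymbolicSeries(
                symbols=shuffled,
                alphabet_size=x.alphabet_size,
                blocks=list(x.blocks),
                site_id=x.site_id,
            )
            null_vals[r] = _estimate(xs, y, params).value
    return {
        "observed": observed,
        "mean": float(null_vals.mean()),
        "sd": float(null_vals.std(ddof=1)) if reps > 1 else 0.0,
        "percentile": float(100.0 * (null_vals < observed).mean()),
        "reps": reps,
    }


# ---------------------------------------------------------------------------
# all-pairs matrix
# ---------------------------------------------------------------------------

def te_matrix(
    series_by_site: dict,
    params: TEParams | None = None,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    blocks_by_site: dict | None = None,
    period_label: str = "all",
) -> pd.DataFrame:
    """Directed TE for every ordered site pair; diagonal defined 0.

    ``series_by_site`` maps site id to a real-valued 1-D series (all the same
    length); each series is quantile-discretized on its own values.  Sites
    whose series cannot be discretized (too short, too few distinct values)
    are dropped with a warning.  Returns a square DataFrame indexed by site
    (rows = source, columns = target).
    """
    params = params or TEParams()
    symbolic: dict = {}
    for sid, series in series_by_site.items():
        blocks = None if blocks_by_site is None else blocks_by_site.get(sid)
        try:
            symbolic[sid] = discretize(
                series, scheme, blocks=blocks, site_id=sid,
                period_label=period_label,
            )
        except ValueError as err:
            warnings.warn(f"site {sid!r} dropped from TE matrix: {err}",
                          stacklevel=2)
    sites = list(symbolic)
    if len(sites) < 2:
        raise ValueError("need at least 2 usable sites for a TE matrix")
    mat = pd.DataFrame(0.0, index=sites, columns=sites)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a in sites:
            for b in sites:
                if a == b:
                    continue
                mat.loc[a, b] = _estimate(symbolic[a], symbolic[b], params).value
    mat.index.name = "from_site"
    mat.columns.name = "to_site"
    return mat
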