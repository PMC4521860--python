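"""Data-driven interpretation thresholds for similarity and particularity.

The calibration procedure takes groups of entities expected to be mutually
similar (e.g. gene families), pools all intra-group comparison values into an
S ("similar") distribution and all inter-group values into an N
("non-similar") distribution, checks with Welch's unequal-variance t-test
that the two distributions actually differ, and then locates three
thresholds from the Tukey box-plot whiskers:

* ``tau_s = max(a, b)`` — above it a pair is confidently similar,
* ``tau_n = min(a, b)`` — below it a pair is confidently non-similar,
* ``tau_opt`` — the scanned value in [tau_n, tau_s] minimising the sum of
  the false-negative proportion in S (values below the threshold) and the
  false-positive proportion in N (values at or above it),

where ``a`` is the lower whisker of S and ``b`` the upper whisker of N.
When the whisker ranges do not overlap (a > b) any threshold between them is
error-free and the midpoint is reported.

The same machinery calibrates a particularity threshold: for each candidate
tau_par, (similarity, particularity, particularity) triples are classified
into the eight sign patterns and the pooled proportion of the two
uninformative patterns ("+ + +" and "- - -") is minimised instead of FP+FN.

The module is organised statsmodels-style: :class:`SimilarityThresholdModel`
and :class:`ParticularityThresholdModel` are built from data and their
``fit()`` returns a :class:`ThresholdResult` carrying the estimates, the
scan curve, the Welch diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError, WelchGateError
from .patterns import UNINFORMATIVE, classify_pattern

logger = logging.getLogger(__name__)

DEFAULT_STEP = 0.005
DEFAULT_ALPHA = 0.05


@dataclass
class LabeledDistributions:
    """Pooled intra-group (S) and inter-group (N) comparison values."""

    s_values: list[float]
    n_values: list[float]
    s_provenance: list[tuple[str, tuple[str, str]]] = field(default_factory=list)
    n_provenance: list[tuple[tuple[str, str], tuple[str, str]]] = field(default_factory=list)
    failed_pairs: int = 0


@dataclass
class WelchTest:
    """Welch's unequal-variance t-test result."""

    statistic: float
    df: float
    pvalue: float

    def __iter__(self):
        return iter((self.statistic, self.df, self.pvalue))


@dataclass
class ThresholdResult:
    """Calibrated thresholds plus the scan curve and diagnostics.

    ``curve`` rows are ``(threshold, fn_proportion, fp_proportion)`` for a
    similarity scan and ``(threshold, prop_ppp, prop_mmm)`` for a
    particularity scan.  ``flat_interval`` is the contiguous scanned range
    attaining the minimal objective; ``tau_opt`` is its left end.
    """

    tau_n: float
    tau_s: float
    tau_opt: float
    flat_interval: tuple[float, float]
    curve: list[tuple[float, float, float]]
    overlap: bool
    objective_min: float
    welch: WelchTest | None = None
    kind: str = "similarity"
    n_s: int = 0
    n_n: int = 0

    @property
    def objective_names(self) -> tuple[str, str]:
        if self.kind == "similarity":
            return ("fn_proportion", "fp_proportion")
        return ("prop_plus_plus_plus", "prop_minus_minus_minus")

    def curve_frame(self) -> pd.DataFrame:
        a, b = self.objective_names
        return pd.DataFrame(self.curve, columns=["threshold", a, b])

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "tau_n": self.tau_n,
            "tau_s": self.tau_s,
            "tau_opt": self.tau_opt,
            "flat_interval": list(self.flat_interval),
            "overlap": self.overlap,
            "objective_min": self.objective_min,
            "n_s": self.n_s,
            "n_n": self.n_n,
            "curve": [list(row) for row in self.curve],
        }
        if self.welch is not None:
            d["welch"] = {
                "statistic": self.welch.statistic,
                "df": self.welch.df,
                "pvalue": self.welch.pvalue,
            }
        return d

    def summary(self) -> str:
        a_name, b_name = self.objective_names
        lines = [
            f"{'Threshold calibration (' + self.kind + ')':^58}",
            "=" * 58,
            f"{'tau_N (non-similar below)':<38}{self.tau_n:>18.6f}",
            f"{'tau_S (similar above)':<38}{self.tau_s:>18.6f}",
            f"{'tau_opt':<38}{self.tau_opt:>18.6f}",
            f"{'flat interval':<38}"
            f"{'[%.4f, %.4f]' % self.flat_interval:>18}",
            f"{'min ' + a_name + ' + ' + b_name:<38}{self.objective_min:>18.6f}",
            f"{'distributions overlap':<38}{str(self.overlap):>18}",
            f"{'n (S, N)':<38}{'%d, %d' % (self.n_s, self.n_n):>18}",
        ]
        if self.welch is not None:
            lines.append(
                f"{'Welch t (df, p)':<38}"
                f"{'%.3f (%.1f, %.2e)' % tuple(self.welch):>18}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the scan curve and thresholds (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.curve_frame()
        a_name, b_name = self.objective_names
        if not frame.empty:
            ax.plot(frame["threshold"], frame[a_name], label=a_name)
            ax.plot(frame["threshold"], frame[b_name], label=b_name)
            ax.plot(
                frame["threshold"],
                frame[a_name] + frame[b_name],
                label="sum",
                linestyle="--",
            )
        for tau, style in ((self.tau_n, ":"), (self.tau_s, ":"), (self.tau_opt, "-")):
            ax.axvline(tau, color="grey", linestyle=style, linewidth=0.8)
        ax.set_xlabel("threshold")
        ax.set_ylabel("proportion")
        ax.legend()
        return ax


@dataclass
class LeaveOneOutResult:
    """Full-set calibration plus one recalibration per omitted group."""

    full: ThresholdResult
    omitted: list[tuple[str, ThresholdResult]]

    @property
    def tau_opts(self) -> list[float]:
        return [res.tau_opt for _, res in self.omitted]

    @property
    def tau_spread(self) -> float:
        taus = self.tau_opts
        return max(taus) - min(taus)


# ---------------------------------------------------------------------------
# building blocks


def build_distributions(
    groups: Mapping[str, Sequence[str]],
    value_fn: Callable[[str, str], float],
) -> LabeledDistributions:
    """Pool intra-group pairs into S and cross-group pairs into N.

    A ``value_fn`` failure on a pair is logged and the pair skipped; the
    skip count is reported on the result.
    """
    if len(groups) < 2:
        raise ConfigurationError("at least two groups are required")
    for gid, members in groups.items():
        if len(members) < 2:
            raise ConfigurationError(f"group {gid!r} has fewer than two entities")
    dist = LabeledDistributions(s_values=[], n_values=[])
    for gid, members in groups.items():
        for a, b in itertools.combinations(members, 2):
            try:
                v = value_fn(a, b)
            except Exception as exc:
                logger.warning("skipping intra-group pair (%s, %s): %s", a, b, exc)
                dist.failed_pairs += 1
                continue
            dist.s_values.append(float(v))
            dist.s_provenance.append((gid, (a, b)))
    for (g1, m1), (g2, m2) in itertools.combinations(groups.items(), 2):
        for a in m1:
            for b in m2:
                try:
                    v = value_fn(a, b)
                except Exception as exc:
                    logger.warning("skipping inter-group pair (%s, %s): %s", a, b, exc)
                    dist.failed_pairs += 1
                    continue
                dist.n_values.append(float(v))
                dist.n_provenance.append(((g1, g2), (a, b)))
    return dist


def welch_test(s: Sequence[float], n: Sequence[float]) -> WelchTest:
    """Welch's two-sided unequal-variance t-test between the S and N samples."""
    s_arr, n_arr = np.asarray(s, dtype=float), np.asarray(n, dtype=float)
    if s_arr.size < 2 or n_arr.size < 2:
        raise DegenerateInputError("Welch's test needs at least two values per side")
    if s_arr.var(ddof=1) == 0.0 and n_arr.var(ddof=1) == 0.0:
        raise DegenerateInputError("both samples have zero variance")
    res = stats.ttest_ind(s_arr, n_arr, equal_var=False)
    return WelchTest(statistic=float(res.statistic), df=float(res.df), pvalue=float(res.pvalue))


def whiskers(values: Sequence[float], mode: str = "tukey") -> tuple[float, float]:
    """Box-plot whiskers of a sample.

    ``"tukey"``: lowest value >= Q1 - 1.5·IQR and highest value <=
    Q3 + 1.5·IQR, with linearly interpolated quartiles.  ``"minmax"``: the
    sample extremes.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("whiskers of an empty sample are undefined")
    if mode == "minmax":
        return float(arr.min()), float(arr.max())
    if mode != "tukey":
        raise ValueError(f"whisker mode must be 'tukey' or 'minmax', got {mode!r}")
    q1, q3 = np.percentile(arr, [25.0, 75.0])
    iqr = q3 - q1
    low_fence, high_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    low = float(arr[arr >= low_fence].min())
    high = float(arr[arr <= high_fence].max())
    return low, high


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive scan grid from lo to hi; endpoints always present."""
    if hi < lo:
        raise ValueError("grid upper bound below lower bound")
    n = int(math.floor((hi - lo) / step + 1e-9))
    pts = lo + step * np.arange(n + 1)
    pts = np.round(pts, 12)
    if pts[-1] < hi - 1e-12:
        pts = np.append(pts, hi)
    else:
        pts[-1] = min(pts[-1], hi)
    return pts


def _minimize_on_grid(
    grid: np.ndarray, objective: np.ndarray, tol: float = 1e-12
) -> tuple[float, tuple[float, float], float]:
    """Smallest grid point attaining the minimum, and its flat plateau."""
    best = objective.min()
    at_min = objective <= best + tol
    first = int(np.argmax(at_min))
    last = first
    while last + 1 < len(grid) and at_min[last + 1]:
        last += 1
    return float(grid[first]), (float(grid[first]), float(grid[last])), float(best)


def scan_similarity_threshold(
    dist: LabeledDistributions,
    step: float = DEFAULT_STEP,
    whisker_mode: str = "tukey",
    welch: WelchTest | None = None,
) -> ThresholdResult:
    """Locate tau_N, tau_S and the FP+FN-minimising tau_opt.

    FN(tau) is the proportion of S strictly below tau; FP(tau) the
    proportion of N at or above tau (a value equal to the threshold counts
    as a positive call).
    """
    if not dist.s_values or not dist.n_values:
        raise DegenerateInputError("both S and N must be non-empty")
    s = np.sort(np.asarray(dist.s_values, dtype=float))
    n = np.sort(np.asarray(dist.n_values, dtype=float))
    a, _ = whiskers(s, mode=whisker_mode)
    _, b = whiskers(n, mode=whisker_mode)
    tau_s, tau_n = max(a, b), min(a, b)
    common = dict(welch=welch, kind="similarity", n_s=len(s), n_n=len(n))
    if a > b:
        return ThresholdResult(
            tau_n=tau_n,
            tau_s=tau_s,
            tau_opt=(a + b) / 2.0,
            flat_interval=(b, a),
            curve=[],
            overlap=False,
            objective_min=0.0,
            **common,
        )
    grid = _grid(tau_n, tau_s, step)
    fn = np.searchsorted(s, grid, side="left") / len(s)
    fp = 1.0 - np.searchsorted(n, grid, side="left") / len(n)
    tau_opt, flat, best = _minimize_on_grid(grid, fn + fp)
    curve = [(float(t), float(x), float(y)) for t, x, y in zip(grid, fn, fp)]
    return ThresholdResult(
        tau_n=tau_n,
        tau_s=tau_s,
        tau_opt=tau_opt,
        flat_interval=flat,
        curve=curve,
        overlap=True,
        objective_min=best,
        **common,
    )


def scan_particularity_threshold(
    triples: Sequence[tuple[float, float, float]],
    tau_sim: float,
    step: float = DEFAULT_STEP,
) -> ThresholdResult:
    """Particularity threshold minimising the uninformative-pattern proportion.

    Scans tau_par over [0, 1]; the objective at each candidate is the pooled
    proportion of "+ + +" plus "- - -" patterns of the triples classified
    with the fixed ``tau_sim``.
    """
    if not triples:
        raise DegenerateInputError("no (sim, par_ab, par_ba) triples provided")
    if not (0.0 <= tau_sim <= 1.0):
        raise ValueError(f"tau_sim must lie in [0, 1], got {tau_sim}")
    arr = np.asarray(triples, dtype=float)
    sim_pos = arr[:, 0] >= tau_sim
    grid = _grid(0.0, 1.0, step)
    total = len(arr)
    prop_ppp = np.empty(len(grid))
    prop_mmm = np.empty(len(grid))
    for i, tau in enumerate(grid):
        par_pos_ab = arr[:, 1] >= tau
        par_pos_ba = arr[:, 2] >= tau
        prop_ppp[i] = np.sum(sim_pos & par_pos_ab & par_pos_ba) / total
        prop_mmm[i] = np.sum(~sim_pos & ~par_pos_ab & ~par_pos_ba) / total
    tau_opt, flat, best = _minimize_on_grid(grid, prop_ppp + prop_mmm)
    curve = [
        (float(t), float(x), float(y)) for t, x, y in zip(grid, prop_ppp, prop_mmm)
    ]
    return ThresholdResult(
        tau_n=0.0,
        tau_s=1.0,
        tau_opt=tau_opt,
        flat_interval=flat,
        curve=curve,
        overlap=True,
        objective_min=best,
        kind="particularity",
        n_s=total,
        n_n=total,
    )


def leave_one_out(
    groups: Mapping[str, Sequence[str]],
    value_fn: Callable[[str, str], float],
    step: float = DEFAULT_STEP,
    whisker_mode: str = "tukey",
) -> LeaveOneOutResult:
    """Recalibrate once per omitted group to gauge threshold stability.

    Pairwise values are memoised so each omission reuses the full-set
    computations.
    """
    if len(groups) < 3:
        raise ConfigurationError("leave-one-out needs at least three groups")
    cache: dict[tuple[str, str], float] = {}

    def cached(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = value_fn(a, b)
        return cache[key]

    def run(sub: Mapping[str, Sequence[str]]) -> ThresholdResult:
        dist = build_distributions(sub, cached)
        w = welch_test(dist.s_values, dist.n_values)
        return scan_similarity_threshold(
            dist, step=step, whisker_mode=whisker_mode, welch=w
        )

    full = run(groups)
    omitted = [
        (gid, run({g: m for g, m in groups.items() if g != gid})) for gid in groups
    ]
    return LeaveOneOutResult(full=full, omitted=omitted)


# ---------------------------------------------------------------------------
# model front-ends


class SimilarityThresholdModel:
    """Similarity-threshold calibration from groups of similar entities.

    Parameters
    ----------
    groups
        Mapping group id -> entity ids; at least two groups of two.
    value_fn
        Pairwise similarity on entity ids, with values in [0, 1].
    step
        Scan grid step (default 0.005).
    alpha
        Welch-gate significance level (two-sided; default 0.05).
    whisker_mode
        ``"tukey"`` (default) or ``"minmax"`` box-plot whiskers.
    """

    def __init__(
        self,
        groups: Mapping[str, Sequence[str]],
        value_fn: Callable[[str, str], float],
        *,
        step: float = DEFAULT_STEP,
        alpha: float = DEFAULT_ALPHA,
        whisker_mode: str = "tukey",
    ) -> None:
        self.groups = dict(groups)
        self.value_fn = value_fn
        self.step = step
        self.alpha = alpha
        self.whisker_mode = whisker_mode
        self.distributions: LabeledDistributions | None = None

    @classmethod
    def from_annotations(
        cls,
        groups: Mapping[str, Sequence[str]],
        gene_terms: Mapping[str, set[str]],
        set_sim: Callable[[Iterable[str], Iterable[str]], float],
        **kwargs,
    ) -> "SimilarityThresholdModel":
        """Build from gene annotation sets and a set-level similarity."""

        def value_fn(a: str, b: str) -> float:
            return set_sim(gene_terms[a], gene_terms[b])

        return cls(groups, value_fn, **kwargs)

    def build(self) -> LabeledDistributions:
        if self.distributions is None:
            self.distributions = build_distributions(self.groups, self.value_fn)
        return self.distributions

    def fit(self, force: bool = False) -> ThresholdResult:
        """Run the Welch gate and the threshold scan.

        Raises :class:`WelchGateError` when S and N are not significantly
        different (p >= alpha); the calibration groups should then be
        redefined.  ``force=True`` scans anyway.
        """
        dist = self.build()
        w = welch_test(dist.s_values, dist.n_values)
        if w.pvalue >= self.alpha and not force:
            raise WelchGateError(
                f"S and N distributions are not significantly different "
                f"(Welch p = {w.pvalue:.4g} >= alpha = {self.alpha}); "
                "redefine the groups or pass force=True"
            )
        return scan_similarity_threshold(
            dist, step=self.step, whisker_mode=self.whisker_mode, welch=w
        )

    def leave_one_out(self) -> LeaveOneOutResult:
        return leave_one_out(
            self.groups, self.value_fn, step=self.step, whisker_mode=self.whisker_mode
        )


class ParticularityThresholdModel:
    """Particularity-threshold calibration from comparison triples.

    Built either directly from ``(sim, par_ab, par_ba)`` triples or from
    groups plus the similarity and particularity functions (all intra- and
    inter-group pairs are pooled).
    """

    def __init__(
        self,
        triples: Sequence[tuple[float, float, float]],
        tau_sim: float,
        *,
        step: float = DEFAULT_STEP,
    ) -> None:
        self.triples = list(triples)
        self.tau_sim = tau_sim
        self.step = step

    @classmethod
    def from_groups(
        cls,
        groups: Mapping[str, Sequence[str]],
        sim_fn: Callable[[str, str], float],
        par_fn: Callable[[str, str], float],
        tau_sim: float,
        **kwargs,
    ) -> "ParticularityThresholdModel":
        entities = [e for members in groups.values() for e in members]
        triples = [
            (sim_fn(a, b), par_fn(a, b), par_fn(b, a))
            for a, b in itertools.combinations(entities, 2)
        ]
        return cls(triples, tau_sim, **kwargs)

    def fit(self) -> ThresholdResult:
        return scan_particularity_threshold(
            self.triples, self.tau_sim, step=self.step
        )


def pattern_proportions(
    triples: Sequence[tuple[float, float, float]], tau_sim: float, tau_par: float
) -> dict[str, float]:
    """Proportion of each of the eight sign patterns among the triples."""
    counts: dict[str, int] = {}
    for sim, pab, pba in triples:
        label = classify_pattern(sim, pab, pba, tau_sim, tau_par)
        counts[label] = counts.get(label, 0) + 1
    total = len(triples)
    return {k: v / total for k, v in counts.items()}


def uninformative_proportion(
    triples: Sequence[tuple[float, float, float]], tau_sim: float, tau_par: float
) -> float:
    """Pooled proportion of the "+ + +" and "- - -" patterns."""
    props = pattern_proportions(triples, tau_sim, tau_par)
    return sum(props.get(p, 0.0) for p in UNINFORMATIVE)
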