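"""Activity matrix, consensus hit calling, selectivity scoring and clustering.

A *consensus hit* is a compound called active (high-confidence curve class
with efficacy > 60%) in every CLL sample, with IC50 below the 30 uM gate in
each.  Selectivity against normal donors is an OR over three clauses:

1. potency: normal-to-CLL geometric-mean IC50 ratio > 5-fold,
2. efficacy: > 40 points mean response-magnitude difference at the two
   highest tested concentrations,
3. majority: low or no activity (not category *active*) in at least half of
   the normal samples.

Activity outcomes are also integer-encoded (active 1, inconclusive 2,
inactive 3, untested 4) and hierarchically clustered on the fraction of
commonly-tested assays in which two compounds' codes disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, leaves_list, to_tree
from scipy.spatial.distance import squareform

from .classify import ACTIVE, INACTIVE, INCONCLUSIVE
from .errors import InsufficientDataError, InvalidArgumentError, LookupFailure

CATEGORY_CODES = {ACTIVE: 1, INCONCLUSIVE: 2, INACTIVE: 3}
UNTESTED_CODE = 4


@dataclass
class ActivityMatrix:
    """Compound x sample grid of (category, curve class, IC50, efficacy)."""

    cells: pd.DataFrame = field(repr=False)  # long: one row per tested compound x sample

    REQUIRED = ("compound_id", "sample_id", "category", "curve_class", "ac50_uM", "efficacy_pct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.cells.columns]
        if missing:
            raise InvalidArgumentError(f"activity matrix missing columns: {missing}")
        dup = self.cells.duplicated(subset=["compound_id", "sample_id"])
        if dup.any():
            raise InvalidArgumentError("duplicate compound x sample cells")

    @property
    def sample_ids(self) -> list[str]:
        return self.cells["sample_id"].drop_duplicates().tolist()

    @property
    def compound_ids(self) -> list[str]:
        return self.cells["compound_id"].drop_duplicates().tolist()

    def require_samples(self, samples: list[str] | tuple[str, ...]) -> None:
        unknown = set(samples) - set(self.sample_ids)
        if unknown:
            raise LookupFailure(f"samples not in matrix: {sorted(unknown)}")

    def pivot(self, column: str) -> pd.DataFrame:
        return self.cells.pivot(index="compound_id", columns="sample_id", values=column)


def activity_matrix_from_fits(classified_fits: pd.DataFrame) -> ActivityMatrix:
    """Build the matrix from a classified fit table (adds no information)."""
    return ActivityMatrix(
        classified_fits[list(ActivityMatrix.REQUIRED)].reset_index(drop=True).copy()
    )


def _geometric_mean(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    return float(np.exp(np.mean(np.log(v)))) if v.size else float("nan")


@dataclass(frozen=True)
class ConsensusHit:
    """Compound pan-active across the CLL samples with all IC50 < the gate."""

    compound_id: str
    ic50s_uM: tuple[float, ...]
    gm_ic50_uM: float
    min_ic50_uM: float
    max_ic50_uM: float


def consensus_hits(
    matrix: ActivityMatrix,
    cll_samples: list[str] | tuple[str, ...],
    ic50_gate_uM: float = 30.0,
) -> list[ConsensusHit]:
    """Compounds active in *every* listed CLL sample with each IC50 < gate.

    Sorted by geometric-mean IC50, most potent first.
    """
    matrix.require_samples(cll_samples)
    cat = matrix.pivot("category")[list(cll_samples)]
    ic50 = matrix.pivot("ac50_uM")[list(cll_samples)]
    ok = (cat == ACTIVE).all(axis=1) & (ic50 < ic50_gate_uM).all(axis=1) & ic50.notna().all(axis=1)
    hits = []
    for cid in cat.index[ok]:
        vals = ic50.loc[cid].to_numpy(dtype=float)
        hits.append(
            ConsensusHit(
                compound_id=cid,
                ic50s_uM=tuple(float(v) for v in vals),
                gm_ic50_uM=_geometric_mean(vals),
                min_ic50_uM=float(vals.min()),
                max_ic50_uM=float(vals.max()),
            )
        )
    return sorted(hits, key=lambda h: (h.gm_ic50_uM, h.compound_id))


def fold_shift(ic50_cll_uM: float, ic50_normal_uM: float) -> float:
    """Potency shift ``ic50_normal / ic50_cll``; > 1 means CLL-selective."""
    if not (ic50_cll_uM > 0 and ic50_normal_uM > 0):
        raise InvalidArgumentError("IC50s must be > 0")
    return ic50_normal_uM / ic50_cll_uM


def efficacy_difference(
    curves: pd.DataFrame,
    compound_id: str,
    cll_samples: list[str] | tuple[str, ...],
    normal_samples: list[str] | tuple[str, ...],
    top_concs_uM: tuple[float, float] | None = None,
) -> float:
    """CLL-minus-normal mean response magnitude at the two top concentrations.

    ``curves`` is the long normalized response table (``compound_id,
    sample_id, conc_uM, response``).  Positive values mean deeper kill in
    CLL samples.
    """
    sub = curves[curves["compound_id"] == compound_id]
    if sub.empty:
        raise LookupFailure(f"compound {compound_id!r} not in response table")
    if top_concs_uM is None:
        concs = np.sort(sub["conc_uM"].unique())
        if concs.size < 2:
            raise InsufficientDataError("need >= 2 tested concentrations")
        top_concs_uM = (float(concs[-2]), float(concs[-1]))
    diffs = []
    for conc in top_concs_uM:
        at = sub[np.isclose(sub["conc_uM"], conc)]
        cll = at[at["sample_id"].isin(cll_samples)]["response"]
        nrm = at[at["sample_id"].isin(normal_samples)]["response"]
        if cll.empty or nrm.empty:
            raise InsufficientDataError(f"missing responses at {conc} uM for {compound_id!r}")
        # magnitude of kill: responses are negative toward kill
        diffs.append(float(np.abs(cll.mean()) - np.abs(nrm.mean())))
    return float(np.mean(diffs))


@dataclass(frozen=True)
class SelectivityResult:
    """Tumor-vs-normal selectivity verdict for one consensus hit."""

    compound_id: str
    fold_shift: float  # NaN when no normal IC50 is defined
    efficacy_diff: float
    n_normal_inactive: int
    n_normal: int
    selective: bool


def call_selectivity(
    matrix: ActivityMatrix,
    consensus: list[ConsensusHit],
    normal_samples: list[str] | tuple[str, ...],
    curves: pd.DataFrame | None = None,
    fold_shift_gate: float = 5.0,
    efficacy_diff_gate: float = 40.0,
    cll_samples: list[str] | tuple[str, ...] | None = None,
) -> list[SelectivityResult]:
    """Evaluate the three-clause selectivity rule for each consensus hit.

    The efficacy clause needs the normalized response table (``curves``);
    without it only the potency and majority clauses are evaluated.
    """
    if not consensus:
        raise InvalidArgumentError("consensus list is empty")
    if not normal_samples:
        raise InvalidArgumentError("need at least one normal sample")
    matrix.require_samples(normal_samples)
    cat = matrix.pivot("category")
    ic50 = matrix.pivot("ac50_uM")
    majority = math.ceil(len(normal_samples) / 2)
    results = []
    for hit in consensus:
        normal_cat = cat.loc[hit.compound_id, list(normal_samples)]
        normal_ic50 = ic50.loc[hit.compound_id, list(normal_samples)]
        gm_normal = _geometric_mean(normal_ic50[normal_cat == ACTIVE].to_numpy(dtype=float))
        shift = gm_normal / hit.gm_ic50_uM if np.isfinite(gm_normal) else float("nan")
        n_inactive = int((normal_cat != ACTIVE).sum())
        if curves is not None and cll_samples is not None:
            eff_diff = efficacy_difference(curves, hit.compound_id, cll_samples, normal_samples)
        else:
            eff_diff = float("nan")
        selective = (
            (np.isfinite(shift) and shift > fold_shift_gate)
            or (np.isfinite(eff_diff) and eff_diff > efficacy_diff_gate)
            or n_inactive >= majority
        )
        results.append(
            SelectivityResult(
                compound_id=hit.compound_id,
                fold_shift=float(shift),
                efficacy_diff=float(eff_diff),
                n_normal_inactive=n_inactive,
                n_normal=len(normal_samples),
                selective=bool(selective),
            )
        )
    return results


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 1) if total else 0.0


def summarize(
    matrix: ActivityMatrix,
    consensus: list[ConsensusHit],
    selectivity: list[SelectivityResult],
    cll_samples: list[str] | tuple[str, ...],
) -> dict:
    """Screen summary: per-sample active counts/%, overall rates, consensus rates."""
    cat = matrix.pivot("category")
    n_tested = int(cat.shape[0])
    per_sample = {}
    for sid in cat.columns:
        counts = cat[sid].value_counts()
        n_active = int(counts.get(ACTIVE, 0))
        per_sample[sid] = {
            "n_active": n_active,
            "pct_active": _pct(n_active, n_tested),
            "n_inconclusive": int(counts.get(INCONCLUSIVE, 0)),
            "n_inactive": int(counts.get(INACTIVE, 0)),
        }
    cll_cat = cat[list(cll_samples)]
    n_inactive_everywhere = int((cll_cat != ACTIVE).all(axis=1).sum())
    n_consensus = len(consensus)
    n_selective = sum(1 for s in selectivity if s.selective)
    n_toxic_normal = n_consensus - n_selective
    return {
        "n_tested": n_tested,
        "per_sample": per_sample,
        "n_inactive_all_cll": n_inactive_everywhere,
        "pct_inactive_all_cll": _pct(n_inactive_everywhere, n_tested),
        "n_consensus": n_consensus,
        "pct_consensus": _pct(n_consensus, n_tested),
        "n_consensus_toxic_to_normal": n_toxic_normal,
        "pct_consensus_toxic_to_normal": _pct(n_toxic_normal, n_consensus),
        "n_selective": n_selective,
        "selective_compounds": sorted(s.compound_id for s in selectivity if s.selective),
    }


def encode_outcomes(matrix: ActivityMatrix) -> pd.DataFrame:
    """Integer-encode outcomes: active 1, inconclusive 2, inactive 3, untested 4."""
    cat = matrix.pivot("category")
    codes = cat.apply(lambda col: col.map(CATEGORY_CODES)).fillna(UNTESTED_CODE).astype(int)
    return codes.sort_index()


def _profile_distance(codes: np.ndarray) -> np.ndarray:
    """Condensed pairwise distance: fraction of commonly-tested assays disagreeing."""
    n = codes.shape[0]
    tested = codes != UNTESTED_CODE
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        both = tested[i] & tested[i + 1:]
        diff = (codes[i] != codes[i + 1:]) & both
        n_both = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(n_both > 0, diff.sum(axis=1) / np.maximum(n_both, 1), 1.0)
        out[k:k + d.size] = d
        k += d.size
    return out


@dataclass
class ClusterResult:
    """Hierarchical clustering of integer activity profiles."""

    order: list[str]  # compound ids in dendrogram leaf order
    linkage: np.ndarray
    codes: pd.DataFrame  # rows reordered to leaf order


def cluster_profiles(codes: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of encoded outcome profiles.

    Rows are sorted by compound id before distance computation so leaf order
    is deterministic; pairs sharing no tested assay get distance 1.
    """
    codes = codes.sort_index()
    if codes.shape[0] < 2:
        return ClusterResult(order=codes.index.tolist(), linkage=np.empty((0, 4)), codes=codes)
    dist = _profile_distance(codes.to_numpy(dtype=int))
    linkage = average(dist)
    order_idx = leaves_list(linkage)
    order = [codes.index[i] for i in order_idx]
    return ClusterResult(order=order, linkage=linkage, codes=codes.loc[order])


def flat_clusters(result: ClusterResult, n_clusters: int) -> pd.Series:
    """Cut the dendrogram into ``n_clusters`` flat clusters (by compound id)."""
    if result.linkage.size == 0:
        return pd.Series([1] * len(result.codes), index=result.codes.index)
    labels = fcluster(result.linkage, t=n_clusters, criterion="maxclust")
    # fcluster labels follow the pre-clustering (sorted) row order
    sorted_ids = sorted(result.codes.index)
    return pd.Series(labels, index=sorted_ids)


def dendrogram_newick(result: ClusterResult) -> str:
    """Newick export of the clustering dendrogram."""
    if result.linkage.size == 0:
        return "(" + ",".join(sorted(result.codes.index)) + ");"
    from skbio.tree import TreeNode

    sorted_ids = sorted(result.codes.index)
    tree = TreeNode.from_linkage_matrix(result.linkage, sorted_ids)
    return str(tree).strip()
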