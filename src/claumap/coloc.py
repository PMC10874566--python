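"""Cross-channel cell pairing, Venn counts and colocalization tables.

Two cells from different channels of the same slice are called colocalized
when their centroids are within ``match_radius_um`` (default 5 um, about one
soma radius).  Matching is greedy globally-nearest: the closest remaining
cross-channel pair is paired first, ties broken by (id_a, id_b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detect import CellSet
from .stack_io import SliceMeta
from . import stats as _stats

__all__ = [
    "DEFAULT_MATCH_RADIUS_UM",
    "PairMatching",
    "ColocCount",
    "match_cells",
    "venn_counts",
    "assign_subdivision",
    "coloc_table",
    "cfos_activation",
]

DEFAULT_MATCH_RADIUS_UM = 5.0


@dataclass
class PairMatching:
    channel_a: str
    channel_b: str
    pairs: list[tuple[int, int, float]]  # (id_a, id_b, distance um)
    unmatched_a: list[int]
    unmatched_b: list[int]
    match_radius_um: float
    meta: SliceMeta = field(default_factory=SliceMeta)

    @property
    def n_a(self) -> int:
        return len(self.pairs) + len(self.unmatched_a)

    @property
    def n_b(self) -> int:
        return len(self.pairs) + len(self.unmatched_b)


@dataclass
class ColocCount:
    """Venn-style counts for one channel pair on one slice."""

    n_a: int
    n_b: int
    n_ab: int
    channel_a: str = ""
    channel_b: str = ""
    meta: SliceMeta = field(default_factory=SliceMeta)

    def __post_init__(self) -> None:
        if self.n_ab > min(self.n_a, self.n_b):
            raise ValueError("n_ab cannot exceed min(n_a, n_b)")

    @property
    def frac_ab_of_a(self) -> float | None:
        """Fraction of A-cells that colocalize with B; absent when n_a = 0."""
        if self.n_a == 0:
            return None
        return self.n_ab / self.n_a


def _same_slice(a: SliceMeta, b: SliceMeta) -> bool:
    return (a.mouse_id, a.slice_id) == (b.mouse_id, b.slice_id)


def match_cells(a: CellSet, b: CellSet, match_radius_um: float = DEFAULT_MATCH_RADIUS_UM) -> PairMatching:
    """Greedy globally-nearest matching of cells across two channels."""
    if not _same_slice(a.meta, b.meta):
        raise ValueError(
            f"cellsets are from different slices: {a.meta.slice_id!r} vs {b.meta.slice_id!r}"
        )
    ids_a = a.cells["id"].to_numpy() if len(a) else np.empty(0, dtype=int)
    ids_b = b.cells["id"].to_numpy() if len(b) else np.empty(0, dtype=int)
    pairs: list[tuple[int, int, float]] = []
    if len(a) and len(b):
        ta, tb = cKDTree(a.xy_um), cKDTree(b.xy_um)
        neighbours = ta.query_ball_tree(tb, r=match_radius_um)
        cand = []
        xy_a, xy_b = a.xy_um, b.xy_um
        for i, js in enumerate(neighbours):
            for j in js:
                d = float(np.hypot(*(xy_a[i] - xy_b[j])))
                cand.append((d, int(ids_a[i]), int(ids_b[j])))
        cand.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for d, ia, jb in cand:
            if ia in used_a or jb in used_b:
                continue
            used_a.add(ia)
            used_b.add(jb)
            pairs.append((ia, jb, d))
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    return PairMatching(
        channel_a=a.channel,
        channel_b=b.channel,
        pairs=pairs,
        unmatched_a=[int(i) for i in ids_a if i not in matched_a],
        unmatched_b=[int(j) for j in ids_b if j not in matched_b],
        match_radius_um=match_radius_um,
        meta=a.meta,
    )


def venn_counts(m: PairMatching) -> ColocCount:
    return ColocCount(
        n_a=m.n_a,
        n_b=m.n_b,
        n_ab=len(m.pairs),
        channel_a=m.channel_a,
        channel_b=m.channel_b,
        meta=m.meta,
    )


def assign_subdivision(ap_mm: float) -> str:
    """Anteroposterior subdivision of a bregma coordinate (mm).

    anterior = (+0.70, +1.80], middle = (-0.20, +0.70], posterior =
    [-1.00, -0.20]; out-of-range coordinates are an error.
    """
    if ap_mm > 0.70:
        if ap_mm <= 1.80:
            return "anterior"
    elif ap_mm > -0.20:
        return "middle"
    elif ap_mm >= -1.00:
        return "posterior"
    raise ValueError(f"ap_mm={ap_mm} outside the claustrum range [-1.00, +1.80]")


def coloc_table(
    slice_cellsets: list[dict[str, CellSet]],
    channel_pairs: list[tuple[str, str]],
    match_radius_um: float = DEFAULT_MATCH_RADIUS_UM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Venn counts per slice plus per-mouse / cohort summaries.

    Returns ``(slice_table, summary_table)``.  Per-mouse means are taken over
    that mouse's slices first; the cohort mean/SD is then taken over mice
    (mouse = statistical unit).  Summaries are given per subdivision and
    pooled (``subdivision == "all"``).
    """
    rows = []
    for sets in slice_cellsets:
        for ca, cb in channel_pairs:
            if ca not in sets or cb not in sets:
                raise KeyError(f"slice is missing channel {ca!r} or {cb!r}")
            cc = venn_counts(match_cells(sets[ca], sets[cb], match_radius_um))
            rows.append(
                {
                    "mouse_id": cc.meta.mouse_id,
                    "slice_id": cc.meta.slice_id,
                    "subdivision": cc.meta.subdivision,
                    "condition": cc.meta.condition,
                    "pair": f"{ca}|{cb}",
                    "n_a": cc.n_a,
                    "n_b": cc.n_b,
                    "n_ab": cc.n_ab,
                    "frac_ab_of_a": cc.frac_ab_of_a,
                }
            )
    slice_table = pd.DataFrame(rows)
    if slice_table.empty:
        return slice_table, pd.DataFrame()
    pooled = slice_table.assign(subdivision="all")
    both = pd.concat([slice_table, pooled], ignore_index=True)
    per_mouse = (
        both.groupby(["pair", "subdivision", "mouse_id"], as_index=False)
        .agg(
            n_a=("n_a", "mean"),
            n_b=("n_b", "mean"),
            n_ab=("n_ab", "mean"),
            frac_ab_of_a=("frac_ab_of_a", "mean"),
        )
    )
    summary = (
        per_mouse.groupby(["pair", "subdivision"], as_index=False)
        .agg(
            mean_n_a=("n_a", "mean"),
            sd_n_a=("n_a", "std"),
            mean_n_b=("n_b", "mean"),
            sd_n_b=("n_b", "std"),
            mean_n_ab=("n_ab", "mean"),
            sd_n_ab=("n_ab", "std"),
            mean_frac=("frac_ab_of_a", "mean"),
            sd_frac=("frac_ab_of_a", "std"),
            n_mice=("mouse_id", "nunique"),
        )
    )
    for c in summary.columns:
        if c.startswith("sd_"):
            summary[c] = summary[c].fillna(0.0)
    return slice_table, summary


def cfos_activation(
    slice_table: pd.DataFrame,
    markers: tuple[str, ...] = ("nurr1", "tle4"),
    cfos_channel: str = "cfos",
    naive_label: str = "naive",
    of_label: str = "of",
) -> pd.DataFrame:
    """c-Fos activation contrast between naive and open-field cohorts.

    ``slice_table`` is the per-slice output of :func:`coloc_table` for pairs
    ``(marker, cfos)`` and must carry condition labels.  Per mouse, the
    percentage of marker+ cells that are c-Fos+ is computed from summed
    counts across slices; mice with zero marker+ cells are excluded with a
    warning.  Group difference (OF minus naive, in percentage points) is
    tested with a pooled unpaired t-test; the reverse percentage (marker+
    among c-Fos+ cells, OF group) is also reported.
    """
    if "condition" not in slice_table.columns or slice_table["condition"].isna().any():
        raise ValueError("slice table must carry condition labels")
    out = []
    for marker in markers:
        pair = f"{marker}|{cfos_channel}"
        sub = slice_table[slice_table["pair"] == pair]
        if sub.empty:
            raise KeyError(f"no rows for pair {pair!r}")
        per_mouse = sub.groupby(["condition", "mouse_id"], as_index=False).agg(
            n_marker=("n_a", "sum"), n_cfos=("n_b", "sum"), n_both=("n_ab", "sum")
        )
        zero = per_mouse["n_marker"] == 0
        if zero.any():
            warnings.warn(
                f"excluding {int(zero.sum())} mice with zero {marker}+ cells", stacklevel=2
            )
            per_mouse = per_mouse[~zero]
        per_mouse = per_mouse.assign(
            pct_cfos_in_marker=100.0 * per_mouse["n_both"] / per_mouse["n_marker"]
        )
        grp = {
            c: per_mouse.loc[per_mouse["condition"] == c, "pct_cfos_in_marker"].to_numpy()
            for c in (naive_label, of_label)
        }
        naive, of = grp[naive_label], grp[of_label]
        res = _stats.unpaired_t(naive, of) if len(naive) >= 2 and len(of) >= 2 else None
        of_rows = per_mouse[per_mouse["condition"] == of_label]
        n_cfos = of_rows["n_cfos"].sum()
        pct_marker_in_cfos = 100.0 * of_rows["n_both"].sum() / n_cfos if n_cfos else np.nan
        out.append(
            {
                "marker": marker,
                "naive_pct": float(naive.mean()) if len(naive) else np.nan,
                "of_pct": float(of.mean()) if len(of) else np.nan,
                "upregulation_points": float(of.mean() - naive.mean())
                if len(naive) and len(of)
                else np.nan,
                "pct_marker_in_cfos_of": float(pct_marker_in_cfos),
                "t": res.t if res else np.nan,
                "df": res.df if res else np.nan,
                "p": res.p if res else np.nan,
                "n_naive": len(naive),
                "n_of": len(of),
            }
        )
    return pd.DataFrame(out)
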