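"""Ensemble-level summaries of side-chain flexibility.

Aggregates per-residue results across accepted apo/holo pairs into the
headline analyses: the distribution of per-site conformational-change
counts, the per-residue-type flexibility probability scale, its correlation
with configurational-entropy differences, unbound-form b-factor/SASA
discrimination of flexible residues, NR-count bookkeeping and the
minimal-rotation fraction among sterically critical residues.  Every
summary is a pure function of the per-residue record table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rotamer import FLEXIBLE, RIGID, ProbabilityEstimate


@dataclass
class SiteChangeHistogram:
    method: str                        # rotamer | delta_chi_60
    counts: dict                       # flexible residues per site -> n sites
    cumulative: dict                   # count -> cumulative fraction of sites

    @property
    def n_sites(self) -> int:
        return sum(self.counts.values())


def site_change_distribution(calls_by_pair: dict, method: str = "rotamer"
                             ) -> SiteChangeHistogram:
    """Histogram of the number of changing residues per binding site.

    ``calls_by_pair`` maps pair id -> either a list of flexibility calls
    (their ``call`` attributes are counted when 'flexible') or a list/array
    of booleans (the 60-degree threshold flags).
    """
    counts: dict[int, int] = {}
    for _pair, calls in sorted(calls_by_pair.items()):
        k = 0
        for c in calls:
            flag = c.call == FLEXIBLE if hasattr(c, "call") else bool(c)
            k += int(flag)
        counts[k] = counts.get(k, 0) + 1
    n = sum(counts.values())
    cum, acc = {}, 0
    for k in range(max(counts) + 1 if counts else 0):
        acc += counts.get(k, 0)
        cum[k] = acc / n
    return SiteChangeHistogram(method=method, counts=dict(sorted(counts.items())),
                               cumulative=cum)


def entropy_correlation(scale: dict, ds_table: dict) -> tuple[float, int]:
    """Pearson r between the flexibility scale and per-type entropy changes.

    ``scale`` maps residue type -> :class:`ProbabilityEstimate` (or a plain
    probability); ``ds_table`` maps residue type -> delta-S.  Computed over
    the intersection of types; requires at least 3 common types.
    """
    common = sorted(set(scale) & set(ds_table))
    if len(common) < 3:
        raise ValueError("need at least 3 residue types in both tables")
    p = [scale[t].p if isinstance(scale[t], ProbabilityEstimate) else float(scale[t])
         for t in common]
    ds = [float(ds_table[t]) for t in common]
    r, _ = sps.pearsonr(p, ds)
    return float(r), len(common)


@dataclass
class GroupComparison:
    quantity: str                      # bfactor | sas_norm
    res_type: str | None               # None for the pooled comparison
    mean_flexible: float
    mean_rigid: float
    n_flexible: int
    n_rigid: int
    t_statistic: float | None          # None when a group is too small
    p_value: float | None

    @property
    def defined(self) -> bool:
        return self.t_statistic is not None


def _welch(flex: np.ndarray, rigid: np.ndarray, quantity: str,
           res_type=None) -> GroupComparison:
    n_f, n_r = len(flex), len(rigid)
    if n_f < 2 or n_r < 2:
        return GroupComparison(quantity, res_type,
                               float(np.mean(flex)) if n_f else np.nan,
                               float(np.mean(rigid)) if n_r else np.nan,
                               n_f, n_r, None, None)
    t, p = sps.ttest_ind(flex, rigid, equal_var=False)
    return GroupComparison(quantity, res_type, float(np.mean(flex)),
                           float(np.mean(rigid)), n_f, n_r, float(t), float(p))


def compare_flexible_vs_rigid(records: pd.DataFrame,
                              quantities=("bfactor", "sas_norm"),
                              per_type: bool = False) -> list[GroupComparison]:
    """Welch two-sided t-tests of unbound-form quantities, flexible vs rigid.

    ``records`` needs columns ``call`` plus the requested quantities; rows
    with excluded calls are ignored.  With ``per_type`` a comparison is also
    emitted for each residue type (column ``res_type``).
    """
    df = records[records["call"].isin([FLEXIBLE, RIGID])]
    out = []
    for q in quantities:
        vals = df.dropna(subset=[q])
        out.append(_welch(vals.loc[vals["call"] == FLEXIBLE, q].to_numpy(),
                          vals.loc[vals["call"] == RIGID, q].to_numpy(), q))
        if per_type:
            for t, sub in vals.groupby("res_type"):
                out.append(_welch(sub.loc[sub["call"] == FLEXIBLE, q].to_numpy(),
                                  sub.loc[sub["call"] == RIGID, q].to_numpy(),
                                  q, t))
    return out


def nr_count_comparison(assignment_pairs) -> tuple[int, int]:
    """(apo NR count, holo NR count) over (apo, holo) assignment pairs."""
    apo_nr = sum(1 for a, _ in assignment_pairs if a.is_nr)
    holo_nr = sum(1 for _, h in assignment_pairs if h.is_nr)
    return apo_nr, holo_nr


@dataclass
class MinimalRotationSummary:
    n_critical: int
    n_minimal: int
    fraction: float | None             # None when nothing is critical
    by_call: dict = field(default_factory=dict)   # call -> (critical, minimal)


def minimal_rotation_summary(criticality_records) -> MinimalRotationSummary:
    """How many sterically critical residues moved by less than 15 degrees."""
    crit = [r for r in criticality_records if r.critical]
    n_min = sum(1 for r in crit if r.minimal_rotation)
    by_call: dict = {}
    for r in crit:
        c = by_call.setdefault(r.flexibility_call or "unknown", [0, 0])
        c[0] += 1
        c[1] += int(bool(r.minimal_rotation))
    frac = n_min / len(crit) if crit else None
    return MinimalRotationSummary(len(crit), n_min, frac,
                                  {k: tuple(v) for k, v in sorted(by_call.items())})


# ---------------------------------------------------------------------------
# hbond aggregation

def hbond_delta_fractions(deltas_with_calls) -> pd.DataFrame:
    """Fractions of residues conserving/gaining/losing bonds per entity,
    split by flexibility call.

    Input rows are (flexibility call, HBondDelta).  Output is indexed by
    (call, entity) with columns conserved/gain/loss summing to 1.
    """
    rows = []
    for call, delta in deltas_with_calls:
        for entity in ("water", "protein", "ligand"):
            rows.append({"call": call, "entity": entity,
                         "outcome": getattr(delta, entity)})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    table = (df.groupby(["call", "entity"])["outcome"]
               .value_counts(normalize=True).unstack(fill_value=0.0))
    for col in ("conserved", "gain", "loss"):
        if col not in table:
            table[col] = 0.0
    return table[["conserved", "gain", "loss"]].sort_index()


# ---------------------------------------------------------------------------
# figures

def plot_report(histogram: SiteChangeHistogram, scale: dict, out_dir) -> list:
    """Write the standard report figures (PNG); returns the paths."""
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ks = sorted(histogram.counts)
    ax.bar(ks, [histogram.counts[k] for k in ks], color="#d95f02")
    ax.set_xlabel("side chains changing rotamer per binding site")
    ax.set_ylabel("number of sites")
    ax2 = ax.twinx()
    ax2.plot(sorted(histogram.cumulative),
             [histogram.cumulative[k] for k in sorted(histogram.cumulative)],
             "k.-", ms=4)
    ax2.set_ylabel("cumulative fraction")
    p = out_dir / "site_change_distribution.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    if scale:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        types = sorted(scale, key=lambda t: -scale[t].p)
        ax.errorbar(range(len(types)), [scale[t].p for t in types],
                    yerr=[scale[t].error for t in types], fmt="o", capsize=3)
        ax.set_xticks(range(len(types)), types, rotation=90, fontsize=7)
        ax.set_ylabel("P(rotamer change)")
        p = out_dir / "flexibility_scale.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
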