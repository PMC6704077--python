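"""The three-principle montage-selection decision procedure.

Principle 1 (lobe selectivity): a montage is a candidate for a pathway if
its max-MCD lobe is the pathway's target lobe and that maximum is not
shared (within relative tolerance) with a non-target lobe; candidates are
ranked by minimal spread.

Principle 2 (minimal overlap): among dorsal/ventral pairs, the pair whose
50%-of-max threshold sets share the fewest nodes wins.  By default only
principle-1 survivors enter the matrix; ``scope="all"`` evaluates every
pair independently, and ``scope="winner_row"`` restricts to pairs that
contain each pathway's top-ranked candidate.

Principle 3 (cluster verification): each winning montage must show at
least one of its pathway's target gyri among its top-k CMCD clusters.

The final pair is the principle-2 winner when both members survive
principle 1 and pass principle 3; otherwise the report explains which
principle failed and names no pair.  The whole report is a deterministic
pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .clusters import GyrusCluster, cluster_by_gyrus, top_clusters
from .io import AtlasLabelTable, FieldVector, MscopeError
from .lobes import Category, LobeStats, lobe_statistics
from .overlap import OverlapResult, ThresholdedSet, all_pairs_overlap, \
    threshold_field

SHARED_MAX_RTOL = 1e-6   # "comparably stimulates" operationalization


@dataclass
class SelectionTargets:
    """Target anatomy for the two pathways.

    Defaults are the reading-network targets: the dorsal (grapho-
    phonological) route peaks in the left parietal lobe around the
    supramarginal gyrus, the ventral (lexico-semantic) route in the left
    temporal lobe around the middle/inferior temporal gyri.
    """

    dorsal_target_lobe: Category = ("left", "parietal")
    dorsal_target_gyri: frozenset[str] = frozenset({"Supramarginal Gyrus"})
    ventral_target_lobe: Category = ("left", "temporal")
    ventral_target_gyri: frozenset[str] = frozenset(
        {"Middle Temporal Gyrus", "Inferior Temporal Gyrus"})
    top_k_for_verification: int = 5

    def __post_init__(self) -> None:
        self.dorsal_target_gyri = frozenset(self.dorsal_target_gyri)
        self.ventral_target_gyri = frozenset(self.ventral_target_gyri)
        if not self.dorsal_target_gyri or not self.ventral_target_gyri:
            raise MscopeError("target gyrus sets must be non-empty")
        if self.top_k_for_verification < 1:
            raise MscopeError("top_k_for_verification must be >= 1")


@dataclass
class Principle1Entry:
    montage_name: str
    max_lobe: Category
    passes_target: bool
    excluded_shared_max: bool
    spread_count: int
    exceedance: dict[Category, float]
    offtarget_exceedance_mass: float

    def to_dict(self) -> dict:
        return {
            "montage_name": self.montage_name,
            "max_lobe": list(self.max_lobe),
            "passes_target": self.passes_target,
            "excluded_shared_max": self.excluded_shared_max,
            "spread_count": self.spread_count,
            "exceedance": {f"{h}/{lb}": v
                           for (h, lb), v in self.exceedance.items()},
            "offtarget_exceedance_mass": self.offtarget_exceedance_mass,
        }


@dataclass
class Principle3Outcome:
    montage_name: str
    verified: bool
    found: dict[str, int]       # target gyrus -> rank among clusters
    top_clusters: list[GyrusCluster]

    def to_dict(self) -> dict:
        return {
            "montage_name": self.montage_name,
            "verified": self.verified,
            "found": self.found,
            "top_clusters": [c.to_dict() for c in self.top_clusters],
        }


@dataclass
class SelectionReport:
    principle1_dorsal: list[Principle1Entry]
    principle1_ventral: list[Principle1Entry]
    dorsal_survivors: list[str]
    ventral_survivors: list[str]
    principle2_matrix: list[OverlapResult]
    winning_pair: tuple[str, str] | None
    winning_n_overlap: int | None
    principle2_tied: bool
    principle3: list[Principle3Outcome] = dc_field(default_factory=list)
    final_pair: tuple[str, str] | None = None
    notes: list[str] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "principle1": {
                "dorsal": [e.to_dict() for e in self.principle1_dorsal],
                "ventral": [e.to_dict() for e in self.principle1_ventral],
                "dorsal_survivors": self.dorsal_survivors,
                "ventral_survivors": self.ventral_survivors,
            },
            "principle2": {
                "matrix": [
                    {"pair": list(r.pair), "n_overlap": r.n_overlap,
                     "p": r.p, "p_2dp": round(r.p, 2)}
                    for r in self.principle2_matrix
                ],
                "winning_pair": list(self.winning_pair)
                if self.winning_pair else None,
                "winning_n_overlap": self.winning_n_overlap,
                "tied": self.principle2_tied,
            },
            "principle3": [o.to_dict() for o in self.principle3],
            "final_pair": list(self.final_pair) if self.final_pair else None,
            "notes": self.notes,
        }


def principle1_screen(stats_by_montage: dict[str, LobeStats],
                      target: Category) -> list[Principle1Entry]:
    """Rank montages by lobe selectivity toward ``target``.

    Survivors (``passes_target`` and not ``excluded_shared_max``) come
    first, ordered by ascending spread count, then ascending off-target
    exceedance mass, then name; non-survivors follow in name order.
    """
    entries = []
    for name in sorted(stats_by_montage):
        st = stats_by_montage[name]
        passes = st.max_lobe == target
        shared = False
        if passes:
            for _, row in st.per_category.iterrows():
                cat = (row["hemisphere"], row["lobe"])
                if cat == target:
                    continue
                if abs(row["mean"] - st.max_value) <= \
                        SHARED_MAX_RTOL * st.max_value:
                    shared = True
                    break
        offmass = sum(v for cat, v in st.exceedance.items() if cat != target)
        entries.append(Principle1Entry(
            montage_name=name, max_lobe=st.max_lobe, passes_target=passes,
            excluded_shared_max=shared, spread_count=st.spread_count,
            exceedance=st.exceedance, offtarget_exceedance_mass=offmass))

    def key(e: Principle1Entry):
        survivor = e.passes_target and not e.excluded_shared_max
        return (0 if survivor else 1, e.spread_count,
                e.offtarget_exceedance_mass, e.montage_name)

    return sorted(entries, key=key)


def survivors(entries: list[Principle1Entry]) -> list[str]:
    return [e.montage_name for e in entries
            if e.passes_target and not e.excluded_shared_max]


def principle2_best_pair(matrix: list[OverlapResult]
                         ) -> tuple[tuple[str, str], int, bool]:
    """The pair with minimal overlap count; lexicographic tie-break.

    Returns (pair, n_overlap, tied) where ``tied`` flags multiple minima.
    """
    if not matrix:
        raise MscopeError("empty overlap matrix")
    nmin = min(r.n_overlap for r in matrix)
    minima = sorted(r.pair for r in matrix if r.n_overlap == nmin)
    return minima[0], nmin, len(minima) > 1


def principle3_verify(clusters: list[GyrusCluster],
                      target_gyri: frozenset[str] | set[str],
                      top_k: int,
                      montage_name: str = "") -> Principle3Outcome:
    """Verified iff at least one target gyrus ranks among the top_k
    clusters; reports every target gyrus found and its rank."""
    if top_k < 1:
        raise MscopeError("top_k must be >= 1")
    top = top_clusters(clusters, top_k)
    found = {c.gyrus: c.rank for c in top if c.gyrus in target_gyri}
    return Principle3Outcome(montage_name=montage_name,
                             verified=bool(found), found=found,
                             top_clusters=top)


def select(dorsal_fields: dict[str, FieldVector],
           ventral_fields: dict[str, FieldVector],
           labels: AtlasLabelTable,
           targets: SelectionTargets | None = None,
           fraction: float = 0.5,
           scope: str = "survivors") -> SelectionReport:
    """Run principles 1-3 over dorsal/ventral montage fields.

    ``scope`` controls which pairs enter the principle-2 matrix:
    ``"survivors"`` (default) uses principle-1 survivors of each pathway,
    ``"winner_row"`` only pairs containing each pathway's top candidate,
    ``"all"`` every supplied pair.
    """
    if not dorsal_fields or not ventral_fields:
        raise MscopeError("need at least one montage per pathway")
    if scope not in ("survivors", "winner_row", "all"):
        raise MscopeError(f"unknown principle-2 scope {scope!r}")
    targets = targets or SelectionTargets()
    notes: list[str] = []

    stats_d = {n: lobe_statistics(f, labels)
               for n, f in dorsal_fields.items()}
    stats_v = {n: lobe_statistics(f, labels)
               for n, f in ventral_fields.items()}
    p1_d = principle1_screen(stats_d, targets.dorsal_target_lobe)
    p1_v = principle1_screen(stats_v, targets.ventral_target_lobe)
    surv_d, surv_v = survivors(p1_d), survivors(p1_v)

    thr = {n: threshold_field(f, fraction)
           for n, f in {**dorsal_fields, **ventral_fields}.items()}
    if scope == "all":
        names_d = sorted(dorsal_fields)
        names_v = sorted(ventral_fields)
    elif scope == "winner_row":
        names_d = surv_d[:1]
        names_v = sorted(ventral_fields) if surv_d else []
    else:
        names_d, names_v = surv_d, surv_v

    report = SelectionReport(
        principle1_dorsal=p1_d, principle1_ventral=p1_v,
        dorsal_survivors=surv_d, ventral_survivors=surv_v,
        principle2_matrix=[], winning_pair=None, winning_n_overlap=None,
        principle2_tied=False, notes=notes)

    if not names_d or not names_v:
        notes.append("principle 1 left a pathway with no candidate montage; "
                     "no pair can be selected")
        return report

    matrix = all_pairs_overlap([thr[n] for n in names_d],
                               [thr[n] for n in names_v])
    pair, nmin, tied = principle2_best_pair(matrix)
    report.principle2_matrix = matrix
    report.winning_pair = pair
    report.winning_n_overlap = nmin
    report.principle2_tied = tied
    if tied:
        notes.append("principle 2 minimum was tied; lexicographically first "
                     "pair reported")

    d_name, v_name = pair
    if d_name not in surv_d or v_name not in surv_v:
        notes.append(f"principle-2 winner ({d_name}, {v_name}) does not "
                     "survive principle 1; no pair selected")
        return report

    outcomes = []
    for name, fv, gyri in (
            (d_name, dorsal_fields[d_name], targets.dorsal_target_gyri),
            (v_name, ventral_fields[v_name], targets.ventral_target_gyri)):
        cl = cluster_by_gyrus(thr[name], fv.restrict(labels.node_id), labels)
        outcomes.append(principle3_verify(
            cl, gyri, targets.top_k_for_verification, montage_name=name))
    report.principle3 = outcomes
    if all(o.verified for o in outcomes):
        report.final_pair = pair
    else:
        failed = [o.montage_name for o in outcomes if not o.verified]
        notes.append("principle 3 verification failed for "
                     + ", ".join(failed) + "; no pair selected")
    return report
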