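"""Synthetic retroposon evolution along a species tree.

The generator emulates the statistical structure the analysis modules
assume: retroposon families with overlapping Gaussian activity periods
insert at uniformly random genomic positions along the branches of a rooted
species tree.  An insertion landing inside an existing element splits the
host into two fragments with continuous consensus coordinates (a ground-truth
nested insertion); every insertion on an internal branch is inherited by all
descendant tips and becomes a presence/absence marker with a known gain
edge.  Missing data, non-specific deletions and a simple incomplete-lineage-
sorting perturbation (discordant fixation of a marker across the speciation
at its gain edge, yielding a non-clade presence set) can be applied to the
matrix afterwards; every perturbation is logged.

Coordinates and labels only are simulated - no nucleotide sequences.  The
time axis matches the activity model: larger values are more recent, the
species-tree root sits at time 0 (an optional root ``length`` acts as a stem
branch), and family activity means live on the same axis as branch
durations.
"""

from __future__ import annotations

import copy
import json
import pathlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .markers import MarkerLocus, MarkerMatrix
from .parsimony import Node, PhyloTree, read_newick, write_newick
from .repeat_io import RepeatAnnotation, RepeatHit, write_repeatmasker_out
from .tint import TinTMatrix

__all__ = [
    "FamilySpec",
    "SimConfig",
    "SyntheticDataset",
    "simulate",
    "emit",
    "simulate_tint_matrix",
    "default_config",
    "load_sim_config",
    "synthesize_locus",
]


@dataclass(frozen=True)
class FamilySpec:
    """One retroposon family: activity period and element geometry.

    ``insertion_rate`` is the expected number of insertions per lineage over
    the family's entire activity period; the realised count on a branch is
    Poisson with mean ``insertion_rate`` times the normal activity mass
    falling within the branch's time interval.
    """

    name: str
    mu: float
    sigma: float
    insertion_rate: float
    element_length: int
    repeat_class: str = "SINE/synthetic"


@dataclass
class SimConfig:
    species_tree: PhyloTree
    families: list[FamilySpec]
    genome_length: int = 200_000
    missing_rate: float = 0.0
    deletion_rate: float = 0.0
    ils_rate: float = 0.0
    min_fragment: int = 30
    outgroup_label: str | None = "Outgroup"
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.missing_rate, self.deletion_rate, self.ils_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for f in self.families:
            if f.sigma <= 0:
                raise ValueError(f"family {f.name}: sigma must be positive")
        for n in self.species_tree.root.postorder():
            if n.parent is not None and (n.length is None or n.length <= 0):
                raise ValueError("species tree branches need positive durations")


@dataclass
class NestingRecord:
    """Ground truth for one guest-into-host split event."""

    guest_family: str
    host_family: str
    guest_copy: int
    host_copy: int
    guest_time: float
    host_time: float
    detectable: bool = True


@dataclass
class SyntheticDataset:
    annotations: dict[str, RepeatAnnotation]
    tint_truth: dict[str, list[NestingRecord]]
    matrix: MarkerMatrix
    gain_edges: dict[str, str]
    true_tree: PhyloTree
    family_counts: dict[str, dict[str, int]]
    perturbations: dict[str, list] = field(default_factory=dict)


class _Element:
    """A (fragment of a) retroposon copy on one lineage's coordinate line."""

    __slots__ = ("eid", "copy", "family", "rclass", "strand",
                 "g1", "g2", "c1", "c2", "time")

    def __init__(self, eid, copy_id, family, rclass, strand, g1, g2, c1, c2, time):
        self.eid, self.copy, self.family, self.rclass = eid, copy_id, family, rclass
        self.strand, self.g1, self.g2, self.c1, self.c2 = strand, g1, g2, c1, c2
        self.time = time

    def clone(self) -> "_Element":
        return _Element(self.eid, self.copy, self.family, self.rclass,
                        self.strand, self.g1, self.g2, self.c1, self.c2, self.time)

    @property
    def length(self) -> int:
        return self.g2 - self.g1 + 1


class _Lineage:
    def __init__(self, genome_length: int):
        self.elements: list[_Element] = []  # sorted by g1
        self.genome_length = genome_length
        self.events: list[dict] = []

    def fork(self) -> "_Lineage":
        child = _Lineage(self.genome_length)
        child.elements = [e.clone() for e in self.elements]
        child.events = list(self.events)
        return child


def _label_internal_nodes(tree: PhyloTree) -> None:
    i = 0
    for node in tree.root.preorder():
        if node.label is None:
            i += 1
            node.label = f"node{i}"


def _insert(
    lineage: _Lineage,
    fam: FamilySpec,
    t: float,
    edge: str,
    copy_counter: list[int],
    min_fragment: int,
    rng: np.random.Generator,
) -> None:
    L = fam.element_length
    pos = int(rng.integers(1, lineage.genome_length + 2))
    copy_counter[0] += 1
    cid = copy_counter[0]
    strand = "+" if rng.random() < 0.5 else "-"
    guest = _Element(cid, cid, fam.name, fam.repeat_class, strand,
                     pos, pos + L - 1, 1, L, t)

    host = None
    for e in lineage.elements:
        if e.g1 < pos <= e.g2:
            host = e
            break
    new_elements: list[_Element] = []
    if host is not None:
        off = pos - host.g1  # length of genomic-left fragment
        right_len = host.length - off
        if off >= min_fragment and right_len >= min_fragment:
            # clean split: host becomes the left fragment, a new record the right
            right = host.clone()
            copy_counter[0] += 1
            right.eid = copy_counter[0]
            right.g1, right.g2 = pos + L, host.g2 + L
            if host.strand == "+":
                right.c1, right.c2 = host.c1 + off, host.c2
                host.c2 = host.c1 + off - 1
            else:
                right.c1, right.c2 = host.c1, host.c2 - off
                host.c1 = host.c2 - off + 1
            host.g2 = pos - 1
            new_elements.append(right)
            lineage.events.append(dict(
                guest_copy=cid, host_copy=host.copy,
                guest_family=fam.name, host_family=host.family,
                guest_time=t, host_time=host.time,
            ))
        elif off >= right_len:
            # right piece too short: host truncated to its left part
            if host.strand == "+":
                host.c2 = host.c1 + off - 1
            else:
                host.c1 = host.c2 - off + 1
            host.g2 = pos - 1
        else:
            # left piece too short: host truncated to its right part
            if host.strand == "+":
                host.c1 = host.c1 + off
            else:
                host.c2 = host.c2 - off
            host.g1, host.g2 = pos + L, host.g2 + L
    for e in lineage.elements:
        if e is host:
            continue
        if e.g1 >= pos:
            e.g1 += L
            e.g2 += L
    new_elements.append(guest)
    lineage.elements.extend(new_elements)
    lineage.elements.sort(key=lambda e: e.g1)
    lineage.genome_length += L


def _branch_insertions(
    fam: FamilySpec, t0: float, t1: float, rng: np.random.Generator
) -> list[float]:
    lo = norm.cdf((t0 - fam.mu) / fam.sigma)
    hi = norm.cdf((t1 - fam.mu) / fam.sigma)
    n = rng.poisson(fam.insertion_rate * (hi - lo))
    if n == 0:
        return []
    u = rng.uniform(lo, hi, size=n)
    return sorted(fam.mu + fam.sigma * norm.ppf(u))


def simulate(config: SimConfig) -> SyntheticDataset:
    """Run the generator; fully reproducible for a fixed ``config.seed``."""
    if not config.families:
        raise ValueError("need at least one family")
    tree = PhyloTree(copy.deepcopy(config.species_tree.root))
    _label_internal_nodes(tree)
    rng = np.random.default_rng(config.seed)
    copy_counter = [0]
    tips: dict[str, _Lineage] = {}
    tip_time: dict[str, float] = {}
    gain_edges: dict[str, str] = {}
    marker_time: dict[str, float] = {}

    def descend(node: Node, lineage: _Lineage, t: float) -> None:
        duration = node.length if node.length is not None else 0.0
        t1 = t + duration
        if duration > 0:
            timed = []
            for fam in config.families:
                for tt in _branch_insertions(fam, t, t1, rng):
                    timed.append((tt, fam))
            timed.sort(key=lambda x: x[0])
            for tt, fam in timed:
                before = copy_counter[0]
                _insert(lineage, fam, tt, node.label, copy_counter,
                        config.min_fragment, rng)
                marker = f"m{before + 1:05d}"
                gain_edges[marker] = node.label
                marker_time[marker] = tt
        if node.is_leaf:
            tips[node.label] = lineage
            tip_time[node.label] = t1
        else:
            for child in node.children:
                descend(child, lineage.fork(), t1)

    descend(tree.root, _Lineage(config.genome_length), 0.0)

    # --- tip annotations and nesting truth --------------------------------
    annotations: dict[str, RepeatAnnotation] = {}
    tint_truth: dict[str, list[NestingRecord]] = {}
    family_counts: dict[str, dict[str, int]] = {}
    for tip, lineage in tips.items():
        hits = []
        for e in lineage.elements:
            age = max(tip_time[tip] - e.time, 0.0)
            hits.append(RepeatHit(
                sequence_id="chr1", genome_start=e.g1, genome_end=e.g2,
                strand=e.strand, family=e.family, repeat_class=e.rclass,
                consensus_start=e.c1, consensus_end=e.c2,
                divergence=round(5.0 * age, 1), score=float(e.length),
                hit_id=str(e.eid),
            ))
        annotations[tip] = RepeatAnnotation(hits, source_label=tip)
        counts: dict[str, int] = {}
        for e in lineage.elements:
            counts[e.family] = counts.get(e.family, 0) + 1
        family_counts[tip] = counts
        tint_truth[tip] = [
            _truth_record(ev, lineage, config.min_fragment)
            for ev in lineage.events
        ]

    # --- marker matrix ----------------------------------------------------
    below: dict[str, frozenset[str]] = {}
    node_by_label: dict[str, Node] = {}
    for node in tree.root.postorder():
        node_by_label[node.label] = node
        if node.is_leaf:
            below[node.label] = frozenset([node.label])
        else:
            below[node.label] = frozenset().union(
                *(below[c.label] for c in node.children)
            )

    markers = sorted(gain_edges)
    taxa = [l.label for l in tree.root.leaves()]
    perturbations: dict[str, list] = {"ils": [], "deletion": [], "missing": []}

    # ILS emulation: a marker arising just before a speciation can stay
    # polymorphic through it and fix discordantly, ending up present in one
    # child lineage of its gain edge plus the sibling lineage - a set that is
    # not a clade of the species tree.  Markers gained on tip branches have
    # no such window and are left alone.
    present_override: dict[str, frozenset[str]] = {}
    for marker in markers:
        if not config.ils_rate or rng.random() >= config.ils_rate:
            continue
        node = node_by_label[gain_edges[marker]]
        if node.is_leaf or node.parent is None:
            continue
        siblings = [s for s in node.parent.children if s is not node]
        child = node.children[int(rng.integers(len(node.children)))]
        sibling = siblings[int(rng.integers(len(siblings)))]
        discordant = below[child.label] | below[sibling.label]
        present_override[marker] = discordant
        perturbations["ils"].append(
            (marker, gain_edges[marker], sorted(discordant))
        )

    states = []
    for taxon in taxa:
        row = []
        for marker in markers:
            present = present_override.get(marker, below[gain_edges[marker]])
            row.append("+" if taxon in present else "-")
        states.append(row)
    for i, taxon in enumerate(taxa):
        for j, marker in enumerate(markers):
            if states[i][j] == "+" and config.deletion_rate and \
                    rng.random() < config.deletion_rate:
                states[i][j] = "d"
                perturbations["deletion"].append((taxon, marker))
            elif config.missing_rate and rng.random() < config.missing_rate:
                states[i][j] = "?"
                perturbations["missing"].append((taxon, marker))

    outgroup = config.outgroup_label
    true_root = tree.root
    if outgroup is not None:
        taxa = taxa + [outgroup]
        states = states + [["-"] * len(markers)]
        true_root = Node(children=[copy.deepcopy(tree.root), Node(label=outgroup)])
    matrix = MarkerMatrix(taxa, markers, states, outgroup=outgroup)
    return SyntheticDataset(
        annotations=annotations,
        tint_truth=tint_truth,
        matrix=matrix,
        gain_edges=gain_edges,
        true_tree=PhyloTree(true_root),
        family_counts=family_counts,
        perturbations=perturbations,
    )


def _truth_record(ev: dict, lineage: _Lineage, min_fragment: int) -> NestingRecord:
    """Classify a recorded split event as still detectable at this tip.

    Detectable means the guest's immediate neighbours on the final
    coordinate line are two adequate fragments of the original host copy
    with continuous consensus coordinates - i.e. no later insertion or
    truncation disturbed the triple.
    """
    rec = NestingRecord(
        guest_family=ev["guest_family"], host_family=ev["host_family"],
        guest_copy=ev["guest_copy"], host_copy=ev["host_copy"],
        guest_time=ev["guest_time"], host_time=ev["host_time"],
    )
    idx = {e.eid: i for i, e in enumerate(lineage.elements)}
    elements = lineage.elements
    i = idx.get(ev["guest_copy"])
    ok = False
    if i is not None and 0 < i < len(elements) - 1:
        g, l, r = elements[i], elements[i - 1], elements[i + 1]
        if (
            g.copy == ev["guest_copy"] and g.c1 == 1
            and l.copy == r.copy == ev["host_copy"]
            and l.strand == r.strand
            and l.length >= min_fragment and r.length >= min_fragment
        ):
            gap = (r.c1 - l.c2 - 1) if l.strand == "+" else (l.c1 - r.c2 - 1)
            ok = gap == 0
    rec.detectable = ok
    return rec


def emit(dataset: SyntheticDataset, directory: str | pathlib.Path) -> dict[str, pathlib.Path]:
    """Write the dataset as files parseable by the other modules.

    One RepeatMasker ``.out`` per tip, the marker matrix as delimited text,
    the true tree as Newick, and the truth ledgers as JSON.
    """
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, pathlib.Path] = {}
    for tip, ann in dataset.annotations.items():
        path = directory / f"{tip}.rm.out"
        with open(path, "w") as fh:
            write_repeatmasker_out(ann, fh)
        written[f"annotation:{tip}"] = path
    from .markers import write_matrix

    path = directory / "markers.tsv"
    with open(path, "w") as fh:
        write_matrix(dataset.matrix, fh)
    written["matrix"] = path
    path = directory / "true_tree.nwk"
    path.write_text(write_newick(dataset.true_tree) + "\n")
    written["tree"] = path
    ledger = {
        "gain_edges": dataset.gain_edges,
        "family_counts": dataset.family_counts,
        "perturbations": dataset.perturbations,
        "nesting": {
            tip: [
                {
                    "guest_family": r.guest_family,
                    "host_family": r.host_family,
                    "guest_copy": r.guest_copy,
                    "host_copy": r.host_copy,
                    "guest_time": r.guest_time,
                    "host_time": r.host_time,
                    "detectable": r.detectable,
                }
                for r in records
            ]
            for tip, records in dataset.tint_truth.items()
        },
    }
    path = directory / "truth.json"
    path.write_text(json.dumps(ledger, indent=1))
    written["truth"] = path
    return written


def simulate_tint_matrix(
    families: list[FamilySpec],
    n_events: int,
    weights: Mapping[str, float] | None = None,
    seed: int = 0,
) -> TinTMatrix:
    """Draw a nesting count matrix mechanistically from known activities.

    For each event a guest family is chosen proportional to its insertion
    rate and an insertion time is drawn from its activity normal; the host is
    then chosen proportional to each family's copy weight times the number of
    its copies already inserted by that time (its activity CDF).  This
    samples the generative story directly - accumulate-then-hit - without
    using the fitted model's closed-form cell probabilities.
    """
    rng = np.random.default_rng(seed)
    F = len(families)
    rates = np.array([f.insertion_rate for f in families], dtype=float)
    rates = rates / rates.sum()
    if weights is None:
        w = np.ones(F)
    else:
        w = np.array([weights[f.name] for f in families], dtype=float)
    mu = np.array([f.mu for f in families])
    sigma = np.array([f.sigma for f in families])
    counts = np.zeros((F, F), dtype=np.int64)
    guests = rng.choice(F, size=n_events, p=rates)
    times = rng.normal(mu[guests], sigma[guests])
    for g, t in zip(guests, times):
        avail = w * norm.cdf((t - mu) / sigma)
        if avail.sum() <= 0:
            continue  # no target copies exist yet: the insertion is not nested
        counts[g, rng.choice(F, p=avail / avail.sum())] += 1
    return TinTMatrix([f.name for f in families], counts)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def default_config(seed: int = 0) -> SimConfig:
    """An 8-tip study-shaped default: three lineage-specific young families,
    three older shared families, branch durations summing to depth 1."""
    newick = ("(((A:0.15,B:0.15):0.2,(C:0.2,D:0.15):0.15):0.3,"
              "((E:0.2,F:0.2):0.2,(G:0.15,H:0.2):0.2):0.25):0.35;")
    tree = read_newick(newick)
    families = [
        FamilySpec("SINE_old1", mu=0.15, sigma=0.25, insertion_rate=60, element_length=240),
        FamilySpec("SINE_old2", mu=0.35, sigma=0.30, insertion_rate=60, element_length=180),
        FamilySpec("SINE_mid", mu=0.65, sigma=0.25, insertion_rate=80, element_length=200),
        FamilySpec("SINE_left", mu=0.95, sigma=0.20, insertion_rate=70, element_length=160),
        FamilySpec("SINE_right", mu=1.00, sigma=0.20, insertion_rate=70, element_length=300),
        FamilySpec("SINE_young", mu=1.25, sigma=0.15, insertion_rate=50, element_length=220),
    ]
    return SimConfig(species_tree=tree, families=families, seed=seed)


def load_sim_config(stream) -> SimConfig:
    """Read a simulator configuration from YAML.

    Expected keys: ``species_tree`` (Newick with branch durations),
    ``families`` (list of name/mu/sigma/insertion_rate/element_length
    mappings) and optionally genome_length, missing_rate, deletion_rate,
    ils_rate, min_fragment, outgroup_label, seed.
    """
    import yaml

    raw = yaml.safe_load(stream.read() if hasattr(stream, "read") else stream)
    tree = read_newick(raw["species_tree"])
    families = [FamilySpec(**f) for f in raw["families"]]
    kwargs = {
        k: raw[k]
        for k in ("genome_length", "missing_rate", "deletion_rate", "ils_rate",
                  "min_fragment", "outgroup_label", "seed")
        if k in raw
    }
    return SimConfig(species_tree=tree, families=families, **kwargs)


# ---------------------------------------------------------------------------
# Schematic locus alignments (for orthology-validation testing)
# ---------------------------------------------------------------------------


def synthesize_locus(
    states: Mapping[str, str],
    locus_id: str = "locus",
    element_length: int = 24,
    flank: int = 15,
    subtype: str = "SINE_syn",
    seed: int = 0,
) -> MarkerLocus:
    """Fabricate a schematic gapped locus alignment from desired states.

    ``states`` maps taxon to one of ``+`` (element present at the orthologous
    columns), ``-`` (clean empty site), ``d`` (non-specific deletion removing
    the site and part of its flanks).  The fabricated alignment is schematic:
    identical flanks across taxa, one shared element block - enough structure
    to exercise orthology validation, with no pretence of sequence evolution.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    flank_left = "".join(rng.choice(alphabet, flank))
    flank_right = "".join(rng.choice(alphabet, flank))
    element = "".join(rng.choice(alphabet, element_length))
    alignment: dict[str, str] = {}
    for taxon, state in states.items():
        if state == "+":
            alignment[taxon] = flank_left + element + flank_right
        elif state == "-":
            alignment[taxon] = flank_left + "-" * element_length + flank_right
        elif state == "d":
            cut = flank // 2
            alignment[taxon] = (
                flank_left[:cut]
                + "-" * (flank - cut + element_length + flank - cut)
                + flank_right[flank - cut:]
            )
        else:
            raise ValueError(f"unknown desired state {state!r}")
    span = (flank, flank + element_length - 1)
    return MarkerLocus(
        locus_id=locus_id,
        alignment=alignment,
        candidate_span=span,
        element_subtype=subtype,
    )
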