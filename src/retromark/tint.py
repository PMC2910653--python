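"""Transposition-in-transposition (TinT) chronology of retroposon families.

A young retroposon can insert into a genomic copy of an older family, but an
extinct family can never insert into copies that did not yet exist.  A guest
insertion splits its host into two fragments whose consensus coordinates are
continuous across the gap; counting such guest-into-host events over all
family pairs therefore carries information about the relative order and
overlap of family activity periods.

The model: family *f* is active at times distributed Normal(mu_f, sigma_f)
on a latent relative axis where larger values are more recent.  A guest from
family *i* inserting at time *t* can only land in host copies of family *j*
already present, whose available target mass is ``w_j * CDF_j(t)``.
Averaging over the guest's insertion time gives the closed form

    P(host = j | guest = i)  proportional to  w_j * Phi((mu_i - mu_j) /
                                              sqrt(sigma_i^2 + sigma_j^2))

and the count matrix is multinomial per guest row.  The axis location and
scale are not identifiable from nesting counts alone, so fits are normalised
to mean(mu) = 0 and mean(sigma) = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .repeat_io import RepeatAnnotation, RepeatHit

__all__ = [
    "TinTEvent",
    "TinTMatrix",
    "ActivityModel",
    "ActivityInterval",
    "ActivityConfig",
    "detect_nested_insertions",
    "build_tint_matrix",
    "estimate_activity",
    "activity_intervals",
    "classify_lineages",
]


@dataclass(frozen=True)
class TinTEvent:
    """One nested insertion: a guest hit between two fragments of one host."""

    guest_hit: RepeatHit
    host_left: RepeatHit
    host_right: RepeatHit

    @property
    def guest_family(self) -> str:
        return self.guest_hit.family

    @property
    def host_family(self) -> str:
        return self.host_left.family


@dataclass
class TinTMatrix:
    """Square count table: ``counts[i, j]`` guests of family i inside hosts j."""

    families: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        F = len(self.families)
        if self.counts.shape != (F, F):
            raise ValueError(f"count table must be {F}x{F}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self) -> str:
        lines = ["guest\\host\t" + "\t".join(self.families)]
        for i, fam in enumerate(self.families):
            lines.append(fam + "\t" + "\t".join(map(str, self.counts[i])))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "TinTMatrix":
        rows = [ln.split("\t") for ln in text.strip().split("\n")]
        families = rows[0][1:]
        counts = [[int(x) for x in r[1:]] for r in rows[1:]]
        return cls(families, np.array(counts))


def detect_nested_insertions(
    annotation: RepeatAnnotation,
    continuity_window: int = 30,
    min_fragment: int = 30,
) -> list[TinTEvent]:
    """Find guest-into-host nested insertions in a coordinate-sorted annotation.

    A nested insertion is a run of three mutually adjacent hits on one
    sequence: two same-family, same-strand host fragments at least
    ``min_fragment`` bp long whose consensus coordinates are continuous
    across the gap (within ``continuity_window`` bp), with exactly one guest
    hit strictly between them.  Two candidate guests between the same host
    fragments are ambiguous and yield no event, and each hit can be the guest
    of at most one event.
    """
    if continuity_window < 0:
        raise ValueError("continuity_window must be non-negative")
    if min_fragment < 1:
        raise ValueError("min_fragment must be at least 1")
    events: list[TinTEvent] = []
    for _, hits in sorted(annotation.by_sequence().items()):
        for left, guest, right in zip(hits, hits[1:], hits[2:]):
            if left.family != right.family or left.strand != right.strand:
                continue
            if left.genome_length < min_fragment or right.genome_length < min_fragment:
                continue
            if not (left.genome_end < guest.genome_start
                    and guest.genome_end < right.genome_start):
                continue
            if left.strand == "+":
                gap = right.consensus_start - left.consensus_end - 1
            else:
                gap = left.consensus_start - right.consensus_end - 1
            if abs(gap) > continuity_window:
                continue
            events.append(TinTEvent(guest, left, right))
    return events


def build_tint_matrix(
    events: Iterable[TinTEvent], families: Sequence[str]
) -> TinTMatrix:
    """Tally events into a guest x host count matrix over ``families``."""
    families = list(families)
    index = {f: i for i, f in enumerate(families)}
    counts = np.zeros((len(families), len(families)), dtype=np.int64)
    for ev in events:
        for fam in (ev.guest_family, ev.host_family):
            if fam not in index:
                raise ValueError(f"event family {fam!r} not in family list")
        counts[index[ev.guest_family], index[ev.host_family]] += 1
    return TinTMatrix(families, counts)


@dataclass
class ActivityConfig:
    """Optimiser settings for :func:`estimate_activity`."""

    n_restarts: int = 10
    sigma_floor: float = 1e-3
    mu_scale: float = 3.0     # spread of random restarts on the latent axis
    sigma_shrinkage: float = 2.0  # ridge on log-sigma dispersion (see below)
    maxiter: int = 500


@dataclass
class ActivityModel:
    """Fitted relative activity periods: one normal per family."""

    families: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    weights: np.ndarray
    log_likelihood: float

    def family_index(self, family: str) -> int:
        return self.families.index(family)


@dataclass(frozen=True)
class ActivityInterval:
    """Central interval of one family's activity density."""

    family: str
    level: float
    lower: float
    upper: float


def _log_likelihood(
    mu: np.ndarray, sigma: np.ndarray, log_w: np.ndarray, counts: np.ndarray
) -> float:
    # Phi((mu_i - mu_j) / sqrt(sigma_i^2 + sigma_j^2)): target availability of
    # host j averaged over guest i's insertion time.
    scale = np.sqrt(sigma[:, None] ** 2 + sigma[None, :] ** 2)
    log_phi = norm.logcdf((mu[:, None] - mu[None, :]) / scale)
    log_num = log_w[None, :] + log_phi
    log_p = log_num - np.logaddexp.reduce(log_num, axis=1, keepdims=True)
    return float(np.sum(counts * log_p))


def estimate_activity(
    matrix: TinTMatrix,
    weights: Mapping[str, float] | None = None,
    config: ActivityConfig | None = None,
    seed: int = 0,
) -> ActivityModel:
    """Fit per-family activity periods to a nesting count matrix by ML.

    ``weights`` gives each family's relative copy abundance (target mass);
    by default it is taken from the family's share of event participation,
    a proxy for genomic copy number when hit totals are unavailable.
    Optimisation is multi-start quasi-Newton (L-BFGS-B on mu and log sigma),
    seeded, followed by normalisation to mean(mu) = 0 and mean(sigma) = 1
    (a pure reparameterisation that leaves the likelihood unchanged).

    Families with neither guest nor host events are unidentifiable and are
    dropped with a warning.
    """
    config = config or ActivityConfig()
    counts = matrix.counts
    active = (counts.sum(axis=0) + counts.sum(axis=1)) > 0
    if not active.all():
        dropped = [f for f, a in zip(matrix.families, active) if not a]
        warnings.warn(
            f"families with no nesting events excluded from activity fit: "
            f"{dropped}",
            stacklevel=2,
        )
        counts = counts[np.ix_(active, active)]
    families = [f for f, a in zip(matrix.families, active) if a]
    F = len(families)
    if F < 2:
        raise ValueError("activity estimation needs at least two identifiable families")
    if counts.sum() < 1:
        raise ValueError("activity estimation needs at least one event")

    if weights is None:
        w = counts.sum(axis=0) + counts.sum(axis=1)
        w = w / w.sum()
    else:
        w = np.array([weights[f] for f in families], dtype=float)
        w = w / w.sum()
    log_w = np.log(w)

    rng = np.random.default_rng(seed)
    floor = config.sigma_floor

    def objective(theta: np.ndarray) -> float:
        mu = theta[:F]
        log_sigma = theta[F:]
        sigma = np.exp(log_sigma) + floor
        # Spreads of the extreme (oldest/youngest) families are only weakly
        # identified by nesting counts and can collapse to the floor; a mild
        # ridge on log-sigma dispersion keeps the fit away from that
        # degenerate boundary without constraining well-identified families.
        penalty = config.sigma_shrinkage * np.sum(
            (log_sigma - log_sigma.mean()) ** 2
        )
        return -_log_likelihood(mu, sigma, log_w, counts) + penalty

    best: optimize.OptimizeResult | None = None
    for _ in range(config.n_restarts):
        theta0 = np.concatenate(
            [rng.normal(0.0, config.mu_scale, F), rng.normal(0.0, 0.5, F)]
        )
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=[(-50.0, 50.0)] * F + [(-8.0, 5.0)] * F,
            options={"maxiter": config.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    mu = best.x[:F]
    sigma = np.exp(best.x[F:]) + floor
    # identifiability normalisation: shift then scale (likelihood-invariant)
    mu = mu - mu.mean()
    s = sigma.mean()
    mu, sigma = mu / s, sigma / s
    sigma = np.maximum(sigma, floor)
    ll = _log_likelihood(mu, sigma, log_w, counts)
    return ActivityModel(families, mu, sigma, w, ll)


def activity_intervals(
    model: ActivityModel, levels: Iterable[float] = (0.5, 0.9)
) -> list[ActivityInterval]:
    """Central probability intervals ``mu +/- z(level) * sigma`` per family.

    ``z(0.5) = 0.6745`` and ``z(0.9) = 1.6449`` (standard normal quantiles);
    any level in (0, 1) is accepted.
    """
    out = []
    for level in levels:
        if not 0.0 < level < 1.0:
            raise ValueError(f"unsupported interval level {level}")
        z = norm.ppf(0.5 + level / 2.0)
        for fam, mu, sigma in zip(model.families, model.mu, model.sigma):
            out.append(
                ActivityInterval(fam, level, float(mu - z * sigma), float(mu + z * sigma))
            )
    return out


def classify_lineages(
    model_a: ActivityModel,
    model_b: ActivityModel,
    shared_families: Iterable[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Partition families into lineage-specific and shared groups.

    Families fitted in only one genome's model are specific to that lineage;
    families in both are shared.  ``shared_families`` may override the
    inferred intersection (e.g. when external evidence identifies homologous
    subfamilies under different names).
    """
    fam_a, fam_b = set(model_a.families), set(model_b.families)
    shared = frozenset(shared_families) if shared_families is not None \
        else frozenset(fam_a & fam_b)
    return {
        "a_specific": frozenset(fam_a - shared),
        "b_specific": frozenset(fam_b - shared),
        "shared": shared,
    }


def activity_table(model: ActivityModel) -> str:
    """Delimited activity summary: family, mu, sigma, 50% and 90% bounds."""
    half = {iv.family: iv for iv in activity_intervals(model, [0.5])}
    nine = {iv.family: iv for iv in activity_intervals(model, [0.9])}
    lines = ["family\tmu\tsigma\tlo50\thi50\tlo90\thi90"]
    order = np.argsort(-model.mu)  # most recent first
    for i in order:
        fam = model.families[i]
        h, n = half[fam], nine[fam]
        lines.append(
            f"{fam}\t{model.mu[i]:.4f}\t{model.sigma[i]:.4f}"
            f"\t{h.lower:.4f}\t{h.upper:.4f}\t{n.lower:.4f}\t{n.upper:.4f}"
        )
    return "\n".join(lines) + "\n"


def plot_chronology(model: ActivityModel, ax=None):
    """Draw the family chronology: 50% ovals and 90% whiskers per family.

    Requires matplotlib; families are stacked oldest at the bottom.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(model.families) + 1))
    order = np.argsort(model.mu)
    half = {iv.family: iv for iv in activity_intervals(model, [0.5])}
    nine = {iv.family: iv for iv in activity_intervals(model, [0.9])}
    for row, i in enumerate(order):
        fam = model.families[i]
        h, n = half[fam], nine[fam]
        ax.plot([n.lower, n.upper], [row, row], color="black", lw=1)
        ax.add_patch(
            Ellipse(((h.lower + h.upper) / 2, row), h.upper - h.lower, 0.6,
                    facecolor="steelblue", edgecolor="black", lw=0.5)
        )
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([model.families[i] for i in order])
    ax.set_xlabel("relative time (recent to the right)")
    ax.set_ylim(-1, len(order))
    return ax
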