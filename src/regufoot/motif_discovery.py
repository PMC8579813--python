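"""De-novo TFBS motif discovery by symmetry-constrained ZOOPS EM.

Bacterial operator sites are typically bound by homodimers and therefore
carry internal symmetry: contiguous palindromes (inverted repeats read as a
single element), tandem (direct) repeats of a short box at a periodicity of
an integer number of DNA helical turns, or two inverted half-sites separated
by a long nonconserved spacer.  This module searches a grid of such
geometries.  For each geometry a zero-or-one-occurrence-per-sequence (ZOOPS)
mixture model is fit by expectation-maximization from many seeded restarts;
the symmetry is enforced by projecting the position weight matrix onto the
constrained manifold in every M-step (tying each column to its symmetric
partner).  Geometries compete on the mean per-column information content of
their modeled columns.

Only the modeled columns (the half-site/unit columns, or all columns of a
contiguous palindrome) carry a probability model; spacer columns are treated
as background, matching the convention of writing a spaced motif as
``GGGAC-(27)-GTCCC``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome_io import UpstreamRegion, reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

#: Mean information content (bits/column) below which a discovered motif is
#: flagged low-confidence.  Calibrated as the 95th percentile of the best
#: motif's mean IC over 200 null training sets of i.i.d. background
#: (20 regions x 300 bp, GC 0.35, palindrome grid, 5 restarts, seed 12345)
#: via calibrate_null_threshold(); recalibrate for very different problem sizes.
DEFAULT_MIN_INFORMATION = 0.81


@dataclass(frozen=True)
class Geometry:
    """One concrete motif geometry on the search grid.

    * palindrome: a contiguous ``width``-bp element, columns tied to the
      reverse complement of their mirror columns.
    * direct_repeat: two identical ``unit``-bp boxes at start-to-start
      distance ``period`` (spacer = period - unit, unmodeled).
    * inverted_repeat_spaced: a ``unit``-bp box and its reverse complement
      separated by ``spacer`` unmodeled bp.
    """

    mode: str
    width: int = 0
    unit: int = 0
    period: int = 0
    spacer: int = 0

    @property
    def span(self) -> int:
        if self.mode == "palindrome":
            return self.width
        if self.mode == "direct_repeat":
            return self.period + self.unit
        if self.mode == "inverted_repeat_spaced":
            return 2 * self.unit + self.spacer
        raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def modeled_offsets(self) -> tuple[int, ...]:
        """Offsets (within the site span) of the columns carrying a PWM."""
        if self.mode == "palindrome":
            return tuple(range(self.width))
        if self.mode == "direct_repeat":
            return tuple(range(self.unit)) + tuple(range(self.period, self.period + self.unit))
        if self.mode == "inverted_repeat_spaced":
            second = self.unit + self.spacer
            return tuple(range(self.unit)) + tuple(range(second, second + self.unit))
        raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_modeled(self) -> int:
        return len(self.modeled_offsets)

    def project_symmetry(self, counts: np.ndarray) -> np.ndarray:
        """Project a (n_modeled, 4) count matrix onto the symmetry manifold
        and column-normalize.

        Tied columns are averaged (the constrained maximum-likelihood
        estimate when column totals are equal) and each tied pair is
        normalized by one shared scalar, so the symmetry relation holds
        bitwise, not just to rounding.
        """

        def norm(v: np.ndarray) -> np.ndarray:
            s = v.sum()
            return v / s if s > 0 else v

        out = np.empty_like(counts, dtype=float)
        if self.mode == "palindrome":
            w = self.width
            for i in range((w + 1) // 2):
                j = w - 1 - i
                v = norm(0.5 * (counts[i] + counts[j][COMPLEMENT_INDEX]))
                out[i] = v
                out[j] = v[COMPLEMENT_INDEX]
        elif self.mode == "direct_repeat":
            u = self.unit
            for k in range(u):
                v = norm(0.5 * (counts[k] + counts[u + k]))
                out[k] = v
                out[u + k] = v
        elif self.mode == "inverted_repeat_spaced":
            u = self.unit
            for k in range(u):
                j = 2 * u - 1 - k  # partner column in the second unit
                v = norm(0.5 * (counts[k] + counts[j][COMPLEMENT_INDEX]))
                out[k] = v
                out[j] = v[COMPLEMENT_INDEX]
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        return out

    def describe(self) -> str:
        if self.mode == "palindrome":
            return f"palindrome/w{self.width}"
        if self.mode == "direct_repeat":
            return f"direct_repeat/u{self.unit}p{self.period}"
        return f"inverted_repeat_spaced/u{self.unit}s{self.spacer}"


@dataclass
class MotifSpec:
    """Search-grid specification for one discovery run.

    Defaults follow the standard operator-site geometry grid: contiguous
    palindromes of 20-24 bp; repeated units of 7-11 bp at a start-to-start
    periodicity of 21 or 32 bp (two or three DNA helical turns); spaced
    inverted repeats with 20-30 bp spacers.
    """

    mode: str = "palindrome"
    width_range: tuple[int, int] = (20, 24)
    unit_range: tuple[int, int] = (7, 11)
    periods: tuple[int, ...] = (21, 32)
    spacer_range: tuple[int, int] = (20, 30)

    def __post_init__(self) -> None:
        if self.mode not in ("palindrome", "direct_repeat", "inverted_repeat_spaced"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "direct_repeat":
            for u in range(self.unit_range[0], self.unit_range[1] + 1):
                for p in self.periods:
                    if p <= u:
                        raise ValueError(f"period {p} must exceed unit width {u}")

    def geometries(self) -> list[Geometry]:
        if self.mode == "palindrome":
            lo, hi = self.width_range
            return [Geometry("palindrome", width=w) for w in range(lo, hi + 1)]
        if self.mode == "direct_repeat":
            lo, hi = self.unit_range
            return [
                Geometry("direct_repeat", unit=u, period=p)
                for u in range(lo, hi + 1)
                for p in self.periods
            ]
        lo, hi = self.unit_range
        slo, shi = self.spacer_range
        return [
            Geometry("inverted_repeat_spaced", unit=u, spacer=s)
            for u in range(lo, hi + 1)
            for s in range(slo, shi + 1)
        ]


@dataclass
class EMState:
    """Parameters and responsibilities of one ZOOPS EM fit."""

    geometry: Geometry
    pwm: np.ndarray  # (n_modeled, 4), columns sum to 1, symmetry-projected
    gamma: float  # prior probability that a region contains a site
    background: np.ndarray  # (4,)
    loglik: float = -np.inf
    posteriors: list[np.ndarray] = field(default_factory=list)  # per region: (P_r, 2)

    def mean_information(self) -> float:
        """Mean per-column information content (bits) of the modeled columns."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.pwm * np.log2(self.pwm / self.background[None, :])
        return float(np.nansum(terms, axis=1).mean())


@dataclass
class SiteCall:
    """Best site location in one training region (region-local coordinates)."""

    region_index: int
    locus_tag: str
    position: int  # 0-based start within the region
    offset: int  # start relative to translation start
    strand: str
    responsibility: float
    site_seq: str


@dataclass
class DiscoveryResult:
    """Outcome of a discovery run: winning geometry, its fit and audit trail."""

    geometry: Geometry
    state: EMState
    sites: list[SiteCall]
    consensus: str
    mean_information: float
    low_confidence: bool
    geometry_scores: dict[str, tuple[float, float]]  # describe -> (loglik, mean IC)
    seed: int
    n_restarts: int


def encode_regions(regions: list[UpstreamRegion]) -> tuple[np.ndarray, np.ndarray]:
    """Encode regions as an int matrix padded with 4 (=N); return (seqs, lengths)."""
    lengths = np.array([len(r) for r in regions])
    seqs = np.full((len(regions), int(lengths.max())), 4, dtype=np.int8)
    for i, r in enumerate(regions):
        seqs[i, : lengths[i]] = [_BASE_INDEX[b] for b in r.seq]
    return seqs, lengths


def _window_scores(seqs: np.ndarray, logratio5: np.ndarray, offsets: tuple[int, ...], span: int) -> np.ndarray:
    """Sum of per-column log probability ratios over every window start.

    seqs: (R, L) int codes 0..4; logratio5: (n_modeled, 5) with the N row 0.
    Returns (R, L - span + 1).
    """
    R, L = seqs.shape
    P = L - span + 1
    scores = np.zeros((R, P))
    for k, off in enumerate(offsets):
        scores += logratio5[k, seqs[:, off : off + P]]
    return scores


def _revcomp_logratio(logratio5: np.ndarray, geometry: Geometry) -> tuple[np.ndarray, tuple[int, ...]]:
    """Log-ratio matrix and offsets for scoring the minus strand on the forward sequence.

    A site on the minus strand occupying forward window [p, p+span) reads, in
    site coordinate j, the complement of forward position p + span - 1 - j.
    """
    span = geometry.span
    offsets = tuple(span - 1 - off for off in geometry.modeled_offsets)
    comp = np.empty_like(logratio5)
    comp[:, :4] = logratio5[:, COMPLEMENT_INDEX]
    comp[:, 4] = logratio5[:, 4]
    return comp, offsets


def em_step(state: EMState, seqs: np.ndarray, lengths: np.ndarray, pseudoweight: float = 0.0) -> EMState:
    # NOTE: pseudoweight 0 keeps the exact EM monotonicity guarantee; a
    # positive value regularizes the PWM but then only the penalized
    # objective is guaranteed non-decreasing.
    """One EM iteration of the ZOOPS model with symmetry projection.

    E-step: responsibilities z(r,p,s) proportional to gamma/(2 W_r) times the
    probability ratio of the window under the PWM versus background, against
    the no-site alternative (1 - gamma).  M-step: expected base counts over
    modeled columns re-estimate the PWM, which is then projected onto the
    geometry's symmetry manifold; gamma is re-estimated as the mean total
    site responsibility.  All densities relative to background, so unmodeled
    and out-of-site positions cancel.
    """
    geometry = state.geometry
    span = geometry.span
    q = state.background
    with np.errstate(divide="ignore"):
        logratio = np.log(state.pwm) - np.log(q)[None, :]
    logratio5 = np.zeros((geometry.n_modeled, 5))
    logratio5[:, :4] = logratio

    fwd = _window_scores(seqs, logratio5, geometry.modeled_offsets, span)
    rc5, rc_offsets = _revcomp_logratio(logratio5, geometry)
    rev = _window_scores(seqs, rc5, rc_offsets, span)

    R, P = fwd.shape
    valid = np.arange(P)[None, :] <= (lengths - span)[:, None]
    n_valid = valid.sum(axis=1)  # W_r; caller guarantees > 0
    fwd = np.where(valid, fwd, -np.inf)
    rev = np.where(valid, rev, -np.inf)

    prior = state.gamma / (2.0 * n_valid)  # per (position, strand)
    with np.errstate(over="ignore"):
        lr_fwd = np.exp(fwd)
        lr_rev = np.exp(rev)
    site_mass = prior * (lr_fwd.sum(axis=1) + lr_rev.sum(axis=1))
    denom = (1.0 - state.gamma) + site_mass
    z_fwd = prior[:, None] * lr_fwd / denom[:, None]
    z_rev = prior[:, None] * lr_rev / denom[:, None]

    loglik = float(np.log(denom).sum())  # relative to the all-background model

    # M-step: expected counts over modeled columns (weighted bincount per column;
    # a minus-strand site reads the complement of the mirrored forward position)
    counts = np.zeros((geometry.n_modeled, 4))
    zf = z_fwd.ravel()
    zr = z_rev.ravel()
    for k, off in enumerate(geometry.modeled_offsets):
        cf = np.bincount(seqs[:, off : off + P].ravel(), weights=zf, minlength=5)[:4]
        off_rc = span - 1 - off
        cr = np.bincount(seqs[:, off_rc : off_rc + P].ravel(), weights=zr, minlength=5)[:4]
        counts[k] += cf + cr[COMPLEMENT_INDEX]

    counts += pseudoweight * q[None, :]
    pwm = geometry.project_symmetry(counts)
    gamma = float(np.clip((z_fwd.sum() + z_rev.sum()) / R, 1e-4, 1.0 - 1e-4))

    posteriors = [np.stack([z_fwd[r], z_rev[r]], axis=1) for r in range(R)]
    return EMState(
        geometry=geometry,
        pwm=pwm,
        gamma=gamma,
        background=q,
        loglik=loglik,
        posteriors=posteriors,
    )


def _seed_pwm_at(geometry: Geometry, seqs: np.ndarray, r: int, p: int) -> np.ndarray:
    """PWM seeded from the window at (region r, position p), smoothed 70/10/10/10."""
    pwm = np.full((geometry.n_modeled, 4), 0.1)
    for k, off in enumerate(geometry.modeled_offsets):
        b = int(seqs[r, p + off])
        if b < 4:
            pwm[k, b] = 0.7
    return geometry.project_symmetry(pwm)


def _symmetry_scores(geometry: Geometry, seqs: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Per-window count of matching tied base pairs (-1 at invalid positions).

    A window containing a true site of this geometry is internally symmetric
    (each tied pair matches up to the site mutation rate), while background
    pairs match only at the chance rate; ranking windows by this score finds
    strong EM starting points.  The score is strand-neutral: the reverse
    complement of a symmetric site is symmetric the same way.
    """
    span = geometry.span
    R, L = seqs.shape
    P = L - span + 1
    scores = np.zeros((R, P))
    if geometry.mode == "palindrome":
        pairs = [(i, span - 1 - i, True) for i in range(span // 2)]
    elif geometry.mode == "direct_repeat":
        pairs = [(k, geometry.period + k, False) for k in range(geometry.unit)]
    else:
        u, s = geometry.unit, geometry.spacer
        pairs = [(k, 2 * u + s - 1 - k, True) for k in range(u)]
    for i, j, comp in pairs:
        a = seqs[:, i : i + P]
        b = seqs[:, j : j + P]
        if comp:
            scores += (a == (3 - b)) & (b < 4)
        else:
            scores += (a == b) & (b < 4)
    valid = np.arange(P)[None, :] <= (lengths - span)[:, None]
    return np.where(valid, scores, -1.0)


def _fit_geometry(
    geometry: Geometry,
    seqs: np.ndarray,
    lengths: np.ndarray,
    background: np.ndarray,
    restarts: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    gamma_init: float,
    pseudoweight: float,
    candidate_factor: int = 4,
) -> EMState:
    # starting-point search: rank all data windows by internal symmetry,
    # seed from the best plus a random complement, advance each by one EM
    # step, and run full EM only from the `restarts` best one-step states --
    # a single random window rarely lands in the basin of a planted site
    n_sym = restarts * candidate_factor
    n_random = restarts * candidate_factor // 2
    sym = _symmetry_scores(geometry, seqs, lengths)
    flat = np.argsort(sym, axis=None, kind="stable")[::-1][:n_sym]
    seed_windows = [np.unravel_index(int(ix), sym.shape) for ix in flat if sym.flat[ix] >= 0]
    valid_r, valid_p = np.nonzero(sym >= 0)
    picks = rng.integers(0, len(valid_r), size=n_random)
    seed_windows += [(int(valid_r[i]), int(valid_p[i])) for i in picks]

    candidates: list[EMState] = []
    for r, p in seed_windows:
        pwm = _seed_pwm_at(geometry, seqs, int(r), int(p))
        state = EMState(geometry=geometry, pwm=pwm, gamma=gamma_init, background=background)
        candidates.append(em_step(state, seqs, lengths, pseudoweight=pseudoweight))
    candidates.sort(key=lambda s: -s.loglik)

    best: EMState | None = None
    for state in candidates[:restarts]:
        prev = state.loglik
        for _it in range(max_iter):
            state = em_step(state, seqs, lengths, pseudoweight=pseudoweight)
            if abs(state.loglik - prev) <= tol * max(1.0, abs(prev)):
                break
            prev = state.loglik
        if best is None or state.loglik > best.loglik:
            best = state
    assert best is not None
    return best


def consensus_string(geometry: Geometry, pwm: np.ndarray) -> str:
    """Consensus with spacer columns written as their length in parentheses."""
    letters = [BASES[int(i)] for i in pwm.argmax(axis=1)]
    if geometry.mode == "palindrome":
        return "".join(letters)
    u = geometry.unit
    gap = geometry.span - 2 * u
    return "".join(letters[:u]) + f"-({gap})-" + "".join(letters[u:])


def best_sites(state: EMState, regions: list[UpstreamRegion], min_responsibility: float = 0.5) -> list[SiteCall]:
    """Per-region maximum-responsibility site (ZOOPS: at most one per region)."""
    geometry = state.geometry
    span = geometry.span
    calls: list[SiteCall] = []
    for r, post in enumerate(state.posteriors):
        total = post.sum()
        if total < min_responsibility:
            continue
        p, s = np.unravel_index(int(post.argmax()), post.shape)
        window = regions[r].seq[p : p + span]
        site_seq = window if s == 0 else reverse_complement(window)
        calls.append(
            SiteCall(
                region_index=r,
                locus_tag=regions[r].locus_tag,
                position=int(p),
                offset=regions[r].offset_start + int(p),
                strand="+" if s == 0 else "-",
                responsibility=float(post[p, s]),
                site_seq=site_seq,
            )
        )
    return calls


def select_geometry(scores: dict[Geometry, tuple[float, float]]) -> Geometry:
    """Pick the geometry maximizing mean modeled-column information content.

    Ties break toward the smaller site span, then lexicographically on the
    description for determinism.
    """
    if not scores:
        raise ValueError("no geometry results to select from")
    return min(scores, key=lambda g: (-scores[g][1], g.span, g.describe()))


def discover(
    regions: list[UpstreamRegion],
    spec: MotifSpec,
    restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    gamma_init: float = 0.8,
    background: np.ndarray | None = None,
    min_information: float = DEFAULT_MIN_INFORMATION,
    pseudoweight: float = 0.0,
) -> DiscoveryResult:
    """Run symmetry-constrained ZOOPS EM over the spec's geometry grid.

    For each geometry, ``restarts`` EM runs are started from seeded data
    windows and the best by log-likelihood kept; geometries then compete on
    mean modeled-column information content.  Regions shorter than a
    geometry's span are excluded from that geometry's fit with a warning.
    The result records the per-geometry scores for audit and is flagged
    low-confidence when the winning motif's mean information content falls
    below ``min_information`` (bits/column).
    """
    if len(regions) < 3:
        raise ValueError("need at least 3 training regions")
    geometries = spec.geometries()
    max_span = max(g.span for g in geometries)
    usable = [r for r in regions if len(r) >= max_span]
    n_short = len(regions) - len(usable)
    if n_short:
        logger.warning("discover: excluded %d region(s) shorter than the maximal span %d", n_short, max_span)
    if not usable:
        raise ValueError("all regions shorter than the maximal motif span")
    seqs, lengths = encode_regions(usable)

    if background is None:
        background = estimate_background(usable)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(geometries))
    fits: dict[Geometry, EMState] = {}
    scores: dict[Geometry, tuple[float, float]] = {}
    for geometry, child in zip(geometries, child_seeds):
        rng = np.random.default_rng(child)
        state = _fit_geometry(
            geometry, seqs, lengths, background, restarts, rng, tol, max_iter, gamma_init, pseudoweight
        )
        fits[geometry] = state
        scores[geometry] = (state.loglik, state.mean_information())

    winner = select_geometry(scores)
    state = fits[winner]
    mean_ic = state.mean_information()
    sites = best_sites(state, usable)
    result = DiscoveryResult(
        geometry=winner,
        state=state,
        sites=sites,
        consensus=consensus_string(winner, state.pwm),
        mean_information=mean_ic,
        low_confidence=mean_ic < min_information,
        geometry_scores={g.describe(): scores[g] for g in geometries},
        seed=seed,
        n_restarts=restarts,
    )
    if result.low_confidence:
        logger.warning("discover: best motif mean IC %.3f below threshold %.3f", mean_ic, min_information)
    return result


def estimate_background(regions: list[UpstreamRegion]) -> np.ndarray:
    """0-order base frequencies of the training regions (N ignored), smoothed.

    Complementary bases are averaged (q(A)=q(T), q(C)=q(G)): sites are
    scanned on both strands, so the background must be strand-symmetric.
    """
    counts = np.ones(4)
    for r in regions:
        for b in r.seq:
            i = _BASE_INDEX[b]
            if i < 4:
                counts[i] += 1
    counts = 0.5 * (counts + counts[COMPLEMENT_INDEX])
    return counts / counts.sum()


def calibrate_null_threshold(
    spec: MotifSpec,
    n_sets: int = 200,
    n_regions: int = 20,
    region_len: int = 300,
    gc: float = 0.35,
    restarts: int = 5,
    seed: int = 0,
    quantile: float = 0.95,
) -> float:
    """Null calibration of the low-confidence flag.

    Runs discovery on ``n_sets`` training sets of pure i.i.d. background and
    returns the given quantile of the best motif's mean information content.
    A discovered motif scoring below this value is indistinguishable from
    what EM extracts from noise at this problem size.
    """
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    ss = np.random.SeedSequence(seed)
    ics = []
    for child in ss.spawn(n_sets):
        rng = np.random.default_rng(child)
        regions = [
            UpstreamRegion(
                locus_tag=f"null_{i}",
                seq="".join(BASES[b] for b in rng.choice(4, size=region_len, p=probs)),
                offset_start=-region_len,
            )
            for i in range(n_regions)
        ]
        res = discover(
            regions, spec, restarts=restarts, seed=int(rng.integers(0, 2**31 - 1)), min_information=np.inf
        )
        ics.append(res.mean_information)
    return float(np.quantile(ics, quantile))
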