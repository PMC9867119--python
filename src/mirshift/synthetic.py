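"""Synthetic-data generators with planted ground truth.

Every pipeline input can be simulated here under the same design as the
heart-failure study this package analyses: two groups (sham vs TAC),
duplicate mRNA libraries and quadruplicate miRNA libraries, a
predominantly *up*-regulated miRNA compartment with two invariant
reference miRNAs, per-site additive log2 repression of targeted mRNAs,
Ago2 peaks covering a controllable fraction of true sites, elevated
conservation over a designated subset of sites, and double-exponential
calcium transients with controllable kinetics, onset jitter and noise.

All generators take an explicit integer seed and are byte-deterministic:
the same seed and parameters always produce identical output.  The planted
truth is returned in a :class:`SimTruth` record so downstream modules can
be validated against it (sensitivity / FDR of DE calls, exact site-count
recovery, shift recovery, overlap fractions, transient-metric recovery).

Background UTR sequence is i.i.d. uniform over {A, C, G, U} with rejection
of accidental seed matches, so the planted site counts are exact: scanning
a generated UTR set recovers the planted sites and nothing else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .clip import ConservationTrack, Peak
from .diffexpr import GROUP_CASE, GROUP_CONTROL, CountMatrix
from .errors import ParameterError
from .readouts import CalciumTrace
from .seedscan import (
    MATCH_TYPES,
    MatureMiRNA,
    SeedSite,
    match_strings,
    scan_sites,
)

#: The two reference miRNAs held unchanged by construction, mirroring the
#: invariant normalizers of the miRNA-seq design.
REFERENCE_MIRNAS = ("miR-126a-3p", "miR-19b-3p")

_BASES = np.array(list("ACGU"))


@dataclass
class SimTruth:
    """Planted ground truth accumulated across generators."""

    mirna_up_ids: set[str] = field(default_factory=set)
    mirna_fold: dict[str, float] = field(default_factory=dict)
    utr_ids: list[str] = field(default_factory=list)
    utr_lengths: dict[str, int] = field(default_factory=dict)
    planted_sites: list[SeedSite] = field(default_factory=list)
    delta_per_site: float = 0.0
    true_log2fc: dict[str, float] = field(default_factory=dict)
    peak_covered_sites: set[SeedSite] = field(default_factory=set)
    conserved_sites: set[SeedSite] = field(default_factory=set)
    transient_truth: dict = field(default_factory=dict)

    def site_counts(self, restrict_to: set[str] | None = None) -> dict[str, int]:
        """Planted sites per gene, optionally restricted to a miRNA id set."""
        counts = {u: 0 for u in self.utr_ids}
        for s in self.planted_sites:
            if restrict_to is not None and s.mirna_id not in restrict_to:
                continue
            counts[s.utr_id] += 1
        return counts


def random_mirnas(
    n: int, seed: int, length: int = 22, ids: list[str] | None = None
) -> list[MatureMiRNA]:
    """Random mature miRNA sequences with pairwise-distinct seed regions.

    Distinct seeds keep planted-site ownership unambiguous (seed-sharing
    family members would let one miRNA's planted site match another's scan).
    """
    if n < 1 or length < 8:
        raise ParameterError("need n >= 1 miRNAs of length >= 8")
    rng = np.random.default_rng(seed)
    seen_seeds: set[str] = set()
    out: list[MatureMiRNA] = []
    if ids is None:
        ids = [f"miR-sim-{i + 1:03d}" for i in range(n)]
    for mid in ids[:n]:
        for _ in range(1000):
            seq = "".join(_BASES[rng.integers(0, 4, size=length)])
            if seq[1:8] not in seen_seeds:
                seen_seeds.add(seq[1:8])
                out.append(MatureMiRNA(mid, seq))
                break
        else:  # pragma: no cover - 4^7 seed space makes this unreachable
            raise RuntimeError("could not draw a distinct seed")
    return out


# ---------------------------------------------------------------------------
# miRNA count tables
# ---------------------------------------------------------------------------

def generate_mirna_counts(
    n_mirna: int,
    n_per_group: int = 4,
    frac_up: float = 0.35,
    fold_mean: float = 2.5,
    dispersion: float = 0.05,
    baseline_mean: float = 500.0,
    seed: int = 0,
    fold_floor: float = 2.0,
) -> tuple[CountMatrix, SimTruth]:
    """Negative-binomial miRNA count matrix with a planted up-set.

    A fraction ``frac_up`` of the non-reference miRNAs get their TAC-group
    mean multiplied by a per-miRNA fold drawn around ``fold_mean`` (never
    below ``fold_floor``).  The first two features are the reference
    miRNAs, unchanged by construction.  Counts follow NB(mean mu,
    variance mu + dispersion * mu^2); per-miRNA baselines are log-normal
    around ``baseline_mean``.
    """
    if n_mirna <= 2:
        raise ParameterError("n_mirna must exceed the 2 reference miRNAs")
    if n_per_group < 2:
        raise ParameterError("need >= 2 replicates per group")
    if not 0 <= frac_up <= 1:
        raise ParameterError("frac_up must lie in [0, 1]")
    if dispersion <= 0:
        raise ParameterError("dispersion must be positive")
    if baseline_mean <= 0:
        raise ParameterError("baseline_mean must be positive")
    if fold_mean < fold_floor:
        raise ParameterError("fold_mean must be >= fold_floor")

    rng = np.random.default_rng(seed)
    ids = list(REFERENCE_MIRNAS) + [
        f"miR-sim-{i + 1:03d}" for i in range(n_mirna - 2)
    ]
    baselines = baseline_mean * rng.lognormal(0.0, 1.0, size=n_mirna)
    baselines[:2] = baseline_mean * 10  # references: abundant and stable

    non_ref = np.arange(2, n_mirna)
    n_up = int(round(frac_up * non_ref.size))
    up_idx = rng.choice(non_ref, size=n_up, replace=False)
    folds = np.ones(n_mirna)
    folds[up_idx] = np.maximum(
        fold_floor, fold_mean * rng.lognormal(0.0, 0.15, size=n_up)
    )

    mu = np.empty((n_mirna, 2 * n_per_group))
    mu[:, :n_per_group] = baselines[:, None]
    mu[:, n_per_group:] = (baselines * folds)[:, None]
    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p).astype(float)
    counts[:2] = np.maximum(counts[:2], 1.0)  # references stay positive

    samples = [f"sham_{i + 1}" for i in range(n_per_group)] + [
        f"tac_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        [GROUP_CONTROL] * n_per_group + [GROUP_CASE] * n_per_group, index=samples
    )
    matrix = CountMatrix(pd.DataFrame(counts, index=ids, columns=samples), groups)
    truth = SimTruth(
        mirna_up_ids={ids[i] for i in up_idx},
        mirna_fold={ids[i]: float(folds[i]) for i in range(n_mirna)},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# UTRs with planted seed sites
# ---------------------------------------------------------------------------

def _place_intervals(
    rng: np.random.Generator, length: int, widths: list[int], gap: int = 2
) -> list[int] | None:
    """Random non-overlapping starts (with margins) or None on failure."""
    chosen: list[tuple[int, int]] = []
    starts: list[int] = []
    for w in widths:
        ok = False
        for _ in range(200):
            s = int(rng.integers(1, length - w))  # keep room for guard bases
            if all(e + gap <= s or s + w + gap <= b for (b, e) in chosen):
                chosen.append((s, s + w))
                starts.append(s)
                ok = True
                break
        if not ok:
            return None
    return starts


def _pick_base(rng: np.random.Generator, exclude: str) -> str:
    allowed = [b for b in "ACGU" if b != exclude]
    return allowed[int(rng.integers(0, len(allowed)))]


def generate_utrs_with_sites(
    n_genes: int,
    utr_len_mean: int,
    mirnas: list[MatureMiRNA],
    max_sites_per_gene: int = 5,
    seed: int = 0,
    min_len: int = 60,
) -> tuple[dict[str, str], SimTruth]:
    """Random-background UTRs with 0..max planted canonical seed sites.

    Site types are drawn uniformly among the four canonical classes and
    owning miRNAs uniformly among ``mirnas``.  The background is
    rejection-sampled (and patched) so that no unplanned seed match to any
    supplied miRNA exists, and guard bases prevent a planted site from
    reading as a stronger type; the planted truth is therefore exact.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be positive")
    if not mirnas:
        raise ParameterError("at least one miRNA is required")
    for m in mirnas:
        if len(m.sequence) < 8:
            raise ParameterError(f"miRNA {m.id} shorter than 8 nt")
    if max_sites_per_gene < 0:
        raise ParameterError("max_sites_per_gene must be >= 0")
    if utr_len_mean < min_len:
        raise ParameterError(f"utr_len_mean must be >= {min_len}")

    strings = {m.id: match_strings(m) for m in mirnas}
    six_of = {m.id: strings[m.id]["6mer"] for m in mirnas}
    if len(set(six_of.values())) != len(mirnas):
        raise ParameterError("supplied miRNAs must have distinct seed regions")
    forbidden = sorted(set(six_of.values()))
    m8base = {m.id: strings[m.id]["7mer-m8"][0] for m in mirnas}

    rng = np.random.default_rng(seed)
    utrs: dict[str, str] = {}
    truth = SimTruth()
    for g in range(n_genes):
        gid = f"gene{g + 1:04d}"
        length = max(min_len, int(round(rng.normal(utr_len_mean, 0.15 * utr_len_mean))))
        n_sites = int(rng.integers(0, max_sites_per_gene + 1))
        seq, sites = _build_utr(
            rng, gid, length, n_sites, mirnas, strings, forbidden, m8base
        )
        utrs[gid] = seq
        truth.utr_ids.append(gid)
        truth.utr_lengths[gid] = len(seq)
        truth.planted_sites.extend(sites)
    return utrs, truth


def _build_utr(
    rng, gid, length, n_sites, mirnas, strings, forbidden, m8base
) -> tuple[str, list[SeedSite]]:
    for _attempt in range(100):
        seq = list(_BASES[rng.integers(0, 4, size=length)])
        plan = [
            (mirnas[int(rng.integers(0, len(mirnas)))], MATCH_TYPES[int(rng.integers(0, 4))])
            for _ in range(n_sites)
        ]
        widths = [len(strings[m.id][ty]) for m, ty in plan]
        starts = _place_intervals(rng, length, widths) if n_sites else []
        if starts is None:
            continue

        protected = np.zeros(length, dtype=bool)
        intended: set[tuple[str, int]] = set()
        sites: list[SeedSite] = []
        for (m, ty), s in zip(plan, starts):
            sstr = strings[m.id][ty]
            seq[s : s + len(sstr)] = list(sstr)
            protected[s : s + len(sstr)] = True
            offset = 1 if ty in ("8mer", "7mer-m8") else 0
            intended.add((strings[m.id]["6mer"], s + offset))
            # guard bases: prevent the planted site reading as a stronger type
            if ty in ("7mer-A1", "6mer") and s > 0:
                seq[s - 1] = _pick_base(rng, m8base[m.id])
                protected[s - 1] = True
            right = s + len(sstr)
            if ty in ("7mer-m8", "6mer") and right < length:
                seq[right] = _pick_base(rng, "A")
                protected[right] = True
            sites.append(SeedSite(gid, s, s + len(sstr), ty, m.id))

        if not _scrub_background(rng, seq, protected, forbidden, intended):
            continue
        # final verification: the scanner recovers the planted sites exactly
        s_out = "".join(seq)
        planted_by_mirna = {}
        for site in sites:
            planted_by_mirna.setdefault(site.mirna_id, set()).add(site)
        ok = True
        for m in mirnas:
            found = set(scan_sites(gid, s_out, m))
            if found != planted_by_mirna.get(m.id, set()):
                ok = False
                break
        if ok:
            return s_out, sorted(sites, key=lambda x: x.start)
    raise RuntimeError(f"could not build UTR {gid} without accidental sites")


def _scrub_background(rng, seq, protected, forbidden, intended) -> bool:
    """Redraw background bases until no unplanned seed match remains.

    Returns False when an unplanned match lies entirely inside protected
    (planted) positions and cannot be patched.
    """
    for _ in range(300):
        s = "".join(seq)
        bad: set[int] = set()
        for f in forbidden:
            i = s.find(f)
            while i != -1:
                if (f, i) not in intended:
                    unprot = [j for j in range(i, i + len(f)) if not protected[j]]
                    if not unprot:
                        return False
                    bad.update(unprot)
                i = s.find(f, i + 1)
        if not bad:
            return True
        for j in bad:
            seq[j] = str(_BASES[int(rng.integers(0, 4))])
    return False


# ---------------------------------------------------------------------------
# mRNA expression with per-site repression
# ---------------------------------------------------------------------------

def generate_mrna_expression(
    utr_truth: SimTruth,
    up_mirnas: set[str],
    delta_per_site: float = -0.2,
    noise_sd: float = 0.25,
    n_per_group: int = 2,
    base_fpkm_mean: float = 20.0,
    seed: int = 0,
    gene_length: int = 1000,
    depth: float = 2e7,
) -> CountMatrix:
    """mRNA counts whose true log2 fold change is delta_per_site x sites.

    A gene's true TAC/sham log2 fold change equals ``delta_per_site`` times
    its number of planted sites for miRNAs in ``up_mirnas`` (zero-site
    genes shift by 0 in truth).  Per-sample abundances are log-normal
    around the group mean (replicate scatter ``noise_sd``, log2 units) and
    read counts are Poisson at sequencing depth ``depth``.  The truth
    record is updated in place (``delta_per_site``, ``true_log2fc``).
    """
    if not utr_truth.utr_ids:
        raise ParameterError("empty truth: generate UTRs first")
    if delta_per_site > 0:
        raise ParameterError("delta_per_site must be <= 0 (repression)")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if n_per_group < 2:
        raise ParameterError("need >= 2 replicates per group")
    if base_fpkm_mean <= 0 or gene_length <= 0 or depth <= 0:
        raise ParameterError("base_fpkm_mean, gene_length and depth must be positive")

    rng = np.random.default_rng(seed)
    genes = list(utr_truth.utr_ids)
    n_genes = len(genes)
    site_counts = utr_truth.site_counts(restrict_to=set(up_mirnas))
    n_sites = np.array([site_counts[g] for g in genes], dtype=float)
    true_lfc = delta_per_site * n_sites
    utr_truth.delta_per_site = float(delta_per_site)
    utr_truth.true_log2fc = dict(zip(genes, true_lfc))

    base_log2 = rng.normal(math.log2(base_fpkm_mean), 1.5, size=n_genes)
    n_samples = 2 * n_per_group
    log2_fpkm = np.empty((n_genes, n_samples))
    log2_fpkm[:, :n_per_group] = base_log2[:, None]
    log2_fpkm[:, n_per_group:] = (base_log2 + true_lfc)[:, None]
    log2_fpkm += rng.normal(0.0, noise_sd, size=log2_fpkm.shape)
    scale = gene_length * depth / 1e9
    counts = rng.poisson(np.exp2(log2_fpkm) * scale).astype(float)

    samples = [f"sham_{i + 1}" for i in range(n_per_group)] + [
        f"tac_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        [GROUP_CONTROL] * n_per_group + [GROUP_CASE] * n_per_group, index=samples
    )
    lengths = pd.Series(float(gene_length), index=genes)
    return CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), groups, lengths
    )


# ---------------------------------------------------------------------------
# Ago2 peaks and conservation
# ---------------------------------------------------------------------------

def generate_ago2_peaks(
    utr_truth: SimTruth,
    site_recall: float = 0.7,
    decoy_rate: float = 1.0,
    height_mean: float = 50.0,
    seed: int = 0,
) -> list[Peak]:
    """Ago2 peaks strictly containing a fraction of the planted sites.

    Each planted site is covered with probability ``site_recall`` by a peak
    extending at least 1 nt beyond both site ends; decoy peaks are placed
    uniformly (``decoy_rate`` peaks per kb of UTR) avoiding planted sites.
    The covered subset is recorded in ``utr_truth.peak_covered_sites``.
    """
    if not 0 <= site_recall <= 1:
        raise ParameterError("site_recall must lie in [0, 1]")
    if decoy_rate < 0:
        raise ParameterError("decoy_rate must be >= 0")
    if height_mean <= 0:
        raise ParameterError("height_mean must be positive")

    rng = np.random.default_rng(seed)
    peaks: list[Peak] = []
    utr_truth.peak_covered_sites = set()
    for site in utr_truth.planted_sites:
        if rng.random() >= site_recall:
            continue
        length = utr_truth.utr_lengths[site.utr_id]
        ext_l = min(int(rng.integers(1, 25)), site.start)
        ext_r = min(int(rng.integers(1, 25)), length - site.end)
        if ext_l < 1 or ext_r < 1:  # site flush with the UTR edge
            continue
        height = float(height_mean * rng.lognormal(0.0, 0.5))
        peaks.append(Peak(site.utr_id, site.start - ext_l, site.end + ext_r, height))
        utr_truth.peak_covered_sites.add(site)

    sites_by_utr: dict[str, list[SeedSite]] = {}
    for site in utr_truth.planted_sites:
        sites_by_utr.setdefault(site.utr_id, []).append(site)
    for uid in utr_truth.utr_ids:
        length = utr_truth.utr_lengths[uid]
        n_decoys = rng.poisson(decoy_rate * length / 1000.0)
        for _ in range(n_decoys):
            width = int(rng.integers(20, 60))
            if width >= length:
                continue
            for _try in range(50):
                start = int(rng.integers(0, length - width))
                end = start + width
                if all(
                    end <= s.start or s.end <= start
                    for s in sites_by_utr.get(uid, [])
                ):
                    peaks.append(
                        Peak(uid, start, end, float(height_mean * rng.lognormal(0.0, 0.5)))
                    )
                    break
    return peaks


def generate_conservation(
    utrs: dict[str, str],
    truth: SimTruth,
    high: float = 0.9,
    low: float = 0.2,
    seed: int = 0,
    noise_sd: float = 0.05,
    conserved_frac: float = 0.5,
) -> ConservationTrack:
    """Per-base conservation scores: high over a designated subset of
    planted sites, low elsewhere, Gaussian noise clipped to [0, 1].

    The conserved subset (each planted site with probability
    ``conserved_frac``) is recorded in ``truth.conserved_sites``.
    """
    if not 0 <= low < high <= 1:
        raise ParameterError("need 0 <= low < high <= 1")
    if noise_sd < 0 or not 0 <= conserved_frac <= 1:
        raise ParameterError("bad noise_sd or conserved_frac")

    rng = np.random.default_rng(seed)
    track = ConservationTrack()
    for uid, seq in utrs.items():
        track.scores[uid] = np.clip(
            rng.normal(low, noise_sd, size=len(seq)), 0.0, 1.0
        )
    truth.conserved_sites = set()
    for site in truth.planted_sites:
        if rng.random() < conserved_frac:
            track.scores[site.utr_id][site.start : site.end] = np.clip(
                rng.normal(high, noise_sd, size=site.end - site.start), 0.0, 1.0
            )
            truth.conserved_sites.add(site)
    return track


# ---------------------------------------------------------------------------
# Calcium line scans
# ---------------------------------------------------------------------------

def transient_kernel(t, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak; 0 for t < 0."""
    if tau_rise <= 0 or tau_decay <= 0 or tau_rise == tau_decay:
        raise ParameterError("need 0 < tau_rise != tau_decay")
    t = np.asarray(t, dtype=float)
    raw = np.where(
        t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0
    )
    t_peak = kernel_peak_time(tau_rise, tau_decay)
    norm = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return raw / norm


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the kernel maximum (closed form)."""
    if tau_rise <= 0 or tau_decay <= 0 or tau_rise == tau_decay:
        raise ParameterError("need 0 < tau_rise != tau_decay")
    return (
        tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    )


def kernel_crossings(
    level: float, tau_rise: float, tau_decay: float
) -> tuple[float, float]:
    """Times where the unit-peak kernel crosses ``level`` (rise, decay)."""
    if not 0 < level < 1:
        raise ParameterError("level must lie in (0, 1)")
    t_peak = kernel_peak_time(tau_rise, tau_decay)

    def f(t):
        return float(transient_kernel(t, tau_rise, tau_decay)) - level

    t_hi = t_peak
    while f(t_hi) > 0:
        t_hi *= 2
    left = brentq(f, 1e-12, t_peak)
    right = brentq(f, t_peak, t_hi)
    return float(left), float(right)


def kernel_fdhm(tau_rise: float, tau_decay: float) -> float:
    """Full duration at half maximum of the noiseless kernel."""
    left, right = kernel_crossings(0.5, tau_rise, tau_decay)
    return right - left


def generate_linescan(
    n_positions: int = 64,
    duration: float = 2000.0,
    dt: float = 1.0,
    f0: float = 100.0,
    amplitude: float = 1.5,
    tau_rise: float = 25.0,
    tau_decay: float = 150.0,
    onset_jitter_sd: float = 0.0,
    noise_sd: float = 0.0,
    n_transients: int = 2,
    seed: int = 0,
) -> tuple[CalciumTrace, SimTruth]:
    """Simulated line-scan recording of calcium transients.

    Fluorescence at position p is
    ``f0 + f0 * amplitude * sum_i kernel(t - onset_i - jitter_p)`` plus
    Gaussian noise; onsets are evenly spaced (one per period
    ``duration / n_transients``, starting at a quarter period so the
    baseline is observable) and per-position jitter is N(0, jitter_sd),
    shared across transients as a fixed property of each position.
    Truth records the amplitude, the noiseless-kernel FDHM, and the
    jitter SD.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if n_positions < 1:
        raise ParameterError("need >= 1 position")
    if f0 <= 0 or amplitude < 0:
        raise ParameterError("f0 must be positive and amplitude nonnegative")
    if onset_jitter_sd < 0 or noise_sd < 0:
        raise ParameterError("jitter and noise SDs must be >= 0")
    if n_transients < 1:
        raise ParameterError("need >= 1 transient")
    _, t_half_right = kernel_crossings(0.5, tau_rise, tau_decay)
    period = duration / n_transients
    if 0.75 * period < t_half_right or duration < 4 * dt:
        raise ParameterError(
            "duration too short to contain a transient with these kinetics"
        )

    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration, dt)
    onsets = [(i + 0.25) * period for i in range(n_transients)]
    jitter = rng.normal(0.0, onset_jitter_sd, size=n_positions)
    values = np.full((times.size, n_positions), float(f0))
    for onset in onsets:
        shifted = times[:, None] - onset - jitter[None, :]
        values += f0 * amplitude * transient_kernel(shifted, tau_rise, tau_decay)
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)
        values = np.clip(values, 0.0, None)

    truth = SimTruth(
        transient_truth={
            "f0": float(f0),
            "amplitude": float(amplitude),
            "fdhm": kernel_fdhm(tau_rise, tau_decay),
            "onset_jitter_sd": float(onset_jitter_sd),
            "onsets": [float(o) for o in onsets],
            "tau_rise": float(tau_rise),
            "tau_decay": float(tau_decay),
        }
    )
    return CalciumTrace(dt=dt, values=values), truth
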