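"""Synthetic labeled marker alignments with known truth.

The generator emulates the statistical structure of multi-species plant
barcode alignments: per-species haplotype structure, planted
group-diagnostic sites, transition/transversion-biased substitution,
configurable intra- vs inter-specific divergence, and a length-variable
poly(T) slippage window that introduces alignment gaps.

Substitution process
--------------------
Per-site independent two-rate process matching the K2P assumptions: a
mutating site becomes the transition partner with probability
kappa / (kappa + 2) and each of the two transversion partners with
probability 1 / (kappa + 2), where kappa is the transition/transversion
*rate* ratio (so the expected transition:transversion *count* ratio is
kappa / 2).

theta parameters are expected *pairwise* divergences: two sequences from
different species differ at ~theta_inter substitutions/site, two
conspecific sequences on different haplotypes at ~theta_intra. Internally,
species ancestors diverge from a uniform-random root at
(theta_inter - theta_intra)/2 each and within-species haplotypes at
theta_intra/2 each, which yields those pairwise expectations (up to
multiple hits, negligible at barcode-scale divergences).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .alignio import LabeledAlignment, SampleMetadata

_BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class SpeciesSpec:
    """One species in a synthetic alignment."""

    name: str
    n_samples: int
    n_haplotypes: int = 1
    origin: str | None = None
    #: exact substitution count separating each extra haplotype from the
    #: species ancestor (overrides the theta_intra draw when given)
    haplotype_subs: tuple[int, ...] | None = None


@dataclasses.dataclass(frozen=True)
class PlantedSite:
    """A group-diagnostic site: every member of ``group`` carries ``state``
    at 1-based ``position``; every non-member carries its transition
    partner (so the diagnostic is strict)."""

    position: int
    group: tuple[str, ...]
    state: str


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    marker: str
    length: int
    species: tuple[SpeciesSpec, ...]
    theta_intra: float = 0.002
    theta_inter: float = 0.02
    kappa: float = 2.0
    diagnostics: tuple[PlantedSite, ...] = ()
    #: poly(T) slippage windows: (start, end, (min_len, max_len)),
    #: 1-based inclusive columns
    polyt: tuple[tuple[int, int, tuple[int, int]], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not (0 <= self.theta_intra < self.theta_inter or (self.theta_intra == self.theta_inter == 0)):
            raise ValueError("require theta_intra < theta_inter")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for spec in self.species:
            if spec.n_samples < spec.n_haplotypes:
                raise ValueError(f"{spec.name}: n_samples < n_haplotypes")
        positions = [p.position for p in self.diagnostics]
        if len(set(positions)) != len(positions):
            raise ValueError("planted positions must be distinct")
        for p in positions:
            if not 1 <= p <= self.length:
                raise ValueError(f"planted position {p} outside alignment")
            for start, end, _ in self.polyt:
                if start <= p <= end:
                    raise ValueError(f"planted position {p} inside poly-T window")


@dataclasses.dataclass(frozen=True)
class SynthTruth:
    """Ground truth of a generated alignment (recomputable)."""

    species_of: dict[str, str]
    origin_of: dict[str, str | None]
    haplotype_of: dict[str, str]  # id -> "<species>|h<k>"
    planted: tuple[PlantedSite, ...]
    n_transitions: int
    n_transversions: int


def _transition(code: np.ndarray) -> np.ndarray:
    return code ^ 2  # A<->G, C<->T


def _mutate(
    parent: np.ndarray,
    p: float,
    kappa: float,
    rng: np.random.Generator,
    frozen: np.ndarray,
) -> tuple[np.ndarray, int, int]:
    """Mutate per-site with probability p; frozen sites never change."""
    child = parent.copy()
    hit = (rng.random(len(parent)) < p) & ~frozen
    idx = np.flatnonzero(hit)
    ts = tv = 0
    for site in idx:
        if rng.random() < kappa / (kappa + 2.0):
            child[site] = parent[site] ^ 2
            ts += 1
        else:
            child[site] = parent[site] ^ (1 if rng.random() < 0.5 else 3)
            tv += 1
    return child, ts, tv


def _mutate_exact(
    parent: np.ndarray,
    k: int,
    kappa: float,
    rng: np.random.Generator,
    frozen: np.ndarray,
) -> tuple[np.ndarray, int, int]:
    """Mutate exactly k distinct allowed sites."""
    allowed = np.flatnonzero(~frozen)
    sites = rng.choice(allowed, size=k, replace=False)
    child = parent.copy()
    ts = tv = 0
    for site in sites:
        if rng.random() < kappa / (kappa + 2.0):
            child[site] = parent[site] ^ 2
            ts += 1
        else:
            child[site] = parent[site] ^ (1 if rng.random() < 0.5 else 3)
            tv += 1
    return child, ts, tv


def generate_alignment(cfg: SynthConfig) -> tuple[LabeledAlignment, SynthTruth]:
    """Generate a labeled alignment plus its ground truth.

    Deterministic for a fixed config (single seeded RNG stream).
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.length
    frozen = np.zeros(L, dtype=bool)
    for site in cfg.diagnostics:
        frozen[site.position - 1] = True
    for start, end, _ in cfg.polyt:
        frozen[start - 1 : end] = True

    root = rng.integers(0, 4, L).astype(np.uint8)
    total_ts = total_tv = 0

    ids: list[str] = []
    seqs: list[str] = []
    species_l: list[str] = []
    origin_l: list[str | None] = []
    hap_of: dict[str, str] = {}

    ancestor_rate = (cfg.theta_inter - cfg.theta_intra) / 2.0
    for spec in cfg.species:
        ancestor, ts, tv = _mutate(root, ancestor_rate, cfg.kappa, rng, frozen)
        total_ts += ts
        total_tv += tv
        # with exact substitution counts, haplotype 1 is the reference the
        # counts are relative to; otherwise every haplotype diverges from
        # the ancestor so conspecific pairs sit at ~theta_intra
        haps = []
        for h in range(spec.n_haplotypes):
            if spec.haplotype_subs is not None:
                if h == 0:
                    haps.append(ancestor)
                    continue
                hap, ts, tv = _mutate_exact(
                    ancestor, spec.haplotype_subs[h - 1], cfg.kappa, rng, frozen
                )
            else:
                hap, ts, tv = _mutate(ancestor, cfg.theta_intra / 2.0, cfg.kappa, rng, frozen)
            total_ts += ts
            total_tv += tv
            haps.append(hap)
        # every haplotype gets at least one carrier; the rest are assigned
        # uniformly at random
        assign = list(range(spec.n_haplotypes))
        assign += list(rng.integers(0, spec.n_haplotypes, spec.n_samples - spec.n_haplotypes))
        for k, hap_idx in enumerate(assign, start=1):
            seq = haps[hap_idx].copy()
            # apply planted diagnostics
            for site in cfg.diagnostics:
                code = _BASES.index(site.state)
                if spec.name in site.group:
                    seq[site.position - 1] = code
                else:
                    seq[site.position - 1] = code ^ 2
            chars = list("".join(_BASES[c] for c in seq))
            for start, end, (lo, hi) in cfg.polyt:
                tract = int(rng.integers(lo, hi + 1))
                width = end - start + 1
                tract = min(tract, width)
                chars[start - 1 : end] = ["T"] * tract + ["-"] * (width - tract)
            rid = f"{spec.name}_{k:03d}"
            ids.append(rid)
            seqs.append("".join(chars))
            species_l.append(spec.name)
            origin_l.append(spec.origin)
            hap_of[rid] = f"{spec.name}|h{hap_idx + 1}"

    aln = LabeledAlignment(
        marker=cfg.marker,
        ids=tuple(ids),
        seqs=tuple(seqs),
        species=tuple(species_l),
        origin=tuple(origin_l),
    )
    truth = SynthTruth(
        species_of=dict(zip(ids, species_l)),
        origin_of=dict(zip(ids, origin_l)),
        haplotype_of=hap_of,
        planted=cfg.diagnostics,
        n_transitions=total_ts,
        n_transversions=total_tv,
    )
    return aln, truth


# ---------------------------------------------------------------------
# network-structure fixture: haplotypes on an additive substitution chain
# ---------------------------------------------------------------------

#: substitution steps of the emulated haplotype genealogy: child, parent,
#: number of substitutions on the connecting branch
NETWORK_CHAIN: tuple[tuple[str, str, int], ...] = (
    ("A. crassna_01", "A. hirta_01", 2),
    ("A. rugosa_01", "A. crassna_01", 4),
    ("A. cumingiana_01", "A. crassna_01", 1),
    ("A. beccariana_01", "A. crassna_01", 1),
    ("A. sinensis_02", "A. rugosa_01", 1),
    ("A. malaccensis_01", "A. beccariana_01", 1),
)


def make_network_fixture(length: int = 600, seed: int = 0) -> tuple[list[str], dict[str, str]]:
    """Haplotype sequences realizing the documented substitution chain.

    Each branch mutates previously untouched sites, so pairwise Hamming
    distances equal path sums on the genealogy (an additive metric).
    Returns (names, name -> sequence).
    """
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, length).astype(np.uint8)
    seqs: dict[str, np.ndarray] = {"A. hirta_01": root}
    used = np.zeros(length, dtype=bool)
    for child, parent, nsub in NETWORK_CHAIN:
        free = np.flatnonzero(~used)
        sites = rng.choice(free, size=nsub, replace=False)
        used[sites] = True
        seq = seqs[parent].copy()
        for site in sites:
            seq[site] = seq[site] ^ 2
        seqs[child] = seq
    names = sorted(seqs)
    return names, {n: "".join(_BASES[c] for c in seqs[n]) for n in names}


# ---------------------------------------------------------------------
# classification panels keyed to the diagnostic loci
# ---------------------------------------------------------------------


def make_paperlike_panel(
    n_chinese: int = 22,
    n_indonesian: int = 6,
    n_indochina: int = 6,
    theta_intra: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[SampleMetadata, str, str]], dict[str, str]]:
    """Mixed commercial-style panel for end-to-end classification tests.

    Returns ``(samples, truth)`` where each sample is
    ``(metadata, matK query, trnL-trnF query)`` with unaligned (gap-free)
    sequences carrying the diagnostic-key states of its class, and truth
    maps sample id -> expected origin call. Deterministic per seed.
    """
    from .diagnostics import reference_alignment, DEFAULT_KEY

    rng = np.random.default_rng(seed)
    matk_ref = reference_alignment("matK")
    trnl_ref = reference_alignment("trnL-trnF")

    def consensus(aln: LabeledAlignment) -> np.ndarray:
        from .distances import encode

        codes = np.stack([encode(s) for s in aln.seqs])
        L = aln.length
        out = np.zeros(L, dtype=np.uint8)
        for c in range(L):
            col = codes[:, c]
            col = col[col < 4]
            vals, cnt = np.unique(col, return_counts=True)
            out[c] = vals[np.argmax(cnt)] if len(vals) else 0
        return out

    matk_bg = consensus(matk_ref)
    trnl_bg = consensus(trnl_ref)

    classes = (
        ["Chinese mainland"] * n_chinese
        + ["Indonesia"] * n_indonesian
        + ["Indochina"] * n_indochina
    )
    key_states = {
        # (matK 249, matK 435, matK 684, trnL 173, trnL 183, trnL 200)
        "Chinese mainland": {"matK": {249: "C", 435: "G", 684: "T"}, "trnL-trnF": {173: "G"}},
        "Indonesia": {"matK": {249: "T", 435: "A", 684: "C"}, "trnL-trnF": {183: "T"}},
        "Indochina": {"matK": {249: "T", 435: "A", 684: "G"}, "trnL-trnF": {200: "A"}},
    }
    # reset refinement loci to non-matching background states first
    neutral = {"trnL-trnF": {173: "C", 183: "G", 200: "T"}}

    samples: list[tuple[SampleMetadata, str, str]] = []
    truth: dict[str, str] = {}
    key_positions = {
        "matK": sorted({p for c in key_states.values() for p in c["matK"]}),
        "trnL-trnF": [173, 183, 200],
    }
    for i, cls in enumerate(classes, start=1):
        sid = f"panel_{i:03d}"

        def build(bg: np.ndarray, marker: str) -> str:
            seq = bg.copy()
            if theta_intra > 0:
                hit = rng.random(len(seq)) < theta_intra
                for pos in key_positions[marker]:
                    hit[pos - 1] = False
                for site in np.flatnonzero(hit):
                    seq[site] = seq[site] ^ 2
            for pos, st in neutral.get(marker, {}).items():
                seq[pos - 1] = _BASES.index(st)
            for pos, st in key_states[cls].get(marker, {}).items():
                seq[pos - 1] = _BASES.index(st)
            return "".join(_BASES[c] for c in seq)

        matk_q = build(matk_bg, "matK")
        trnl_q = build(trnl_bg, "trnL-trnF")
        meta = SampleMetadata(id=sid, species=None, origin=None, source="synthetic market")
        samples.append((meta, matk_q, trnl_q))
        truth[sid] = cls
    return samples, truth
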