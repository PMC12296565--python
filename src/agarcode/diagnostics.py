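"""Diagnostic-locus discovery and the fixed-locus classification key.

A diagnostic site is an alignment column where one group of sequences is
fixed for a base that is absent outside the group. The shipped key applies
the three discriminative loci on matK:

* +249 = C  ->  Chinese mainland origin (A. sinensis / A. yunnanensis)
* +435 = G  ->  A. sinensis
* +684 = T  ->  A. sinensis

optionally refined by three loci on trnL-trnF (+173, +183, +200) that
place a sample into a biogeographic origin cluster, plus seven auxiliary
matK clustering loci. Both matK species-tier rules must agree for a
species call; a one-of-two match is reported as ambiguous with the
conflict recorded. trnL-trnF rules refine origin only and never override
a matK species call.

All "+N" positions are 1-based columns of the bundled per-marker reference
alignments (synthetic fixtures; see ``agarcode/data``). Unaligned queries
are mapped onto that frame by global pairwise alignment, in either
orientation, before any locus is read.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .alignio import LabeledAlignment, SampleMetadata, read_labeled_fasta
from .distances import encode

_BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class DiagnosticSite:
    """One group-diagnostic column of a reference alignment."""

    marker: str
    position: int  # 1-based reference-alignment column
    group: str
    state: str
    mode: str  # "strict" | "near"
    coverage: float  # fraction of group members carrying state
    exclusivity: float  # fraction of non-members NOT carrying state


@dataclasses.dataclass(frozen=True)
class KeyRule:
    marker: str
    position: int
    state: str
    tier: str  # "species" | "origin" | "refine" | "cluster"
    label: str


@dataclasses.dataclass(frozen=True)
class DiagnosticKey:
    rules: tuple[KeyRule, ...]

    def __post_init__(self) -> None:
        seen = set()
        for rule in self.rules:
            k = (rule.marker, rule.position)
            if k in seen:
                raise ValueError(f"duplicate rule for {k}")
            seen.add(k)

    def tier(self, tier: str, marker: str | None = None) -> tuple[KeyRule, ...]:
        return tuple(
            r for r in self.rules
            if r.tier == tier and (marker is None or r.marker == marker)
        )


def load_key(path: str | Path) -> DiagnosticKey:
    """Load a key file (TSV: marker, position, state, tier, label)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    rules = tuple(
        KeyRule(r.marker, int(r.position), r.state, r.tier, r.label)
        for r in df.itertuples(index=False)
    )
    return DiagnosticKey(rules=rules)


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("agarcode").joinpath("data", name)))


@lru_cache(maxsize=None)
def reference_alignment(marker: str) -> LabeledAlignment:
    """Bundled synthetic reference alignment defining the +N frame."""
    fname = {"matK": "matk_reference_synthetic.fasta",
             "trnL-trnF": "trnl_trnf_reference_synthetic.fasta"}.get(marker)
    if fname is None:
        raise ValueError(f"no bundled reference alignment for marker {marker!r}")
    return read_labeled_fasta(_data_path(fname), marker=marker)


@lru_cache(maxsize=None)
def default_key() -> DiagnosticKey:
    return load_key(_data_path("diagnostic_key.tsv"))


# module-level alias used by callers that just want the shipped key
class _LazyKey:
    def __getattr__(self, item):
        return getattr(default_key(), item)


DEFAULT_KEY = _LazyKey()


# ---------------------------------------------------------------------
# site scanning
# ---------------------------------------------------------------------


def scan_diagnostic_sites(
    aln: LabeledAlignment,
    target_group: str | tuple[str, ...],
    mode: str = "strict",
    tau: float = 0.05,
) -> list[DiagnosticSite]:
    """Scan the alignment for columns diagnostic of ``target_group``.

    ``target_group`` is a species label (or tuple of labels pooled into one
    group). Only columns where every sequence carries an unambiguous base
    are considered. Strict mode demands fixation inside the group and total
    absence of the state outside; near mode relaxes both to ``1 - tau``.
    """
    if mode not in ("strict", "near"):
        raise ValueError("mode must be 'strict' or 'near'")
    groups = (target_group,) if isinstance(target_group, str) else tuple(target_group)
    in_group = np.array([sp in groups for sp in aln.species])
    if in_group.sum() == 0:
        raise ValueError(f"group {groups} absent from alignment")
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("group and complement each need >= 2 sequences")
    codes = np.stack([encode(s) for s in aln.seqs])
    mask = (codes < 4).all(axis=0)
    label = "+".join(groups)
    out: list[DiagnosticSite] = []
    g = codes[in_group]
    c = codes[~in_group]
    for col in np.flatnonzero(mask):
        gcol = g[:, col]
        # candidate state: the group's majority base
        vals, cnts = np.unique(gcol, return_counts=True)
        state = int(vals[np.argmax(cnts)])
        coverage = float((gcol == state).mean())
        exclusivity = float((c[:, col] != state).mean())
        if mode == "strict":
            ok = coverage == 1.0 and exclusivity == 1.0
        else:
            ok = coverage >= 1.0 - tau and exclusivity >= 1.0 - tau
        if ok:
            out.append(
                DiagnosticSite(
                    marker=aln.marker,
                    position=int(col) + 1,
                    group=label,
                    state=_BASES[state],
                    mode=mode,
                    coverage=coverage,
                    exclusivity=exclusivity,
                )
            )
    return out


# ---------------------------------------------------------------------
# query -> reference mapping
# ---------------------------------------------------------------------


@lru_cache(maxsize=None)
def reference_consensus(marker: str) -> str:
    """Majority-base consensus of the reference alignment (gap-free, one
    character per alignment column)."""
    aln = reference_alignment(marker)
    codes = np.stack([encode(s) for s in aln.seqs])
    out = []
    for col in range(aln.length):
        vals = codes[:, col]
        vals = vals[vals < 4]
        if len(vals) == 0:
            out.append("N")
            continue
        uniq, cnt = np.unique(vals, return_counts=True)
        out.append(_BASES[int(uniq[np.argmax(cnt)])])
    return "".join(out)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


class MappingError(ValueError):
    """Query could not be placed on the marker's reference frame."""


def map_to_reference(query: str, marker: str) -> dict[int, str]:
    """Map an unaligned query onto reference-alignment columns.

    Returns ``{1-based column: query base}``; columns deleted in the query
    are absent from the map (read as indeterminate). Both orientations are
    tried and the higher-scoring one used. Identity below 70% over the
    aligned columns is an error.
    """
    query = query.upper().replace("U", "T").replace("-", "")
    if len(query) < 100:
        raise MappingError("query shorter than 100 bases")
    ref = reference_consensus(marker)
    aligner = _aligner()
    best = None
    for orient in (query, str(Seq(query).reverse_complement())):
        aln = aligner.align(ref, orient)[0]
        if best is None or aln.score > best[0].score:
            best = (aln, orient)
    aln, orient = best
    column_map: dict[int, str] = {}
    matches = 0
    aligned_cols = 0
    ref_blocks, q_blocks = aln.aligned
    for (rs, re), (qs, qe) in zip(ref_blocks, q_blocks):
        for k in range(re - rs):
            rpos, qpos = rs + k, qs + k
            column_map[rpos + 1] = orient[qpos]
            aligned_cols += 1
            if ref[rpos] == orient[qpos]:
                matches += 1
    if aligned_cols == 0 or matches / aligned_cols < 0.70:
        raise MappingError(
            f"query does not match marker {marker} "
            f"(identity {0 if aligned_cols == 0 else matches / aligned_cols:.2f})"
        )
    return column_map


# ---------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------

UNRESOLVED_CHINESE = "unresolved (A. sinensis / A. yunnanensis)"

#: pedigree maps; "results" follows the lineage description
#: (Chinese C1/C2 <-> A. sinensis, Indonesian B <-> A. malaccensis,
#: Indochina A <-> A. cumingiana); "abstract" follows the alternative
#: composition (C1: A. sinensis; C2: other Chinese; B: Indonesia;
#: A: Indochina).
PEDIGREE_MAPS = ("results", "abstract")


@dataclasses.dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    evidence: tuple[dict, ...]
    species_call: str  # label, "unresolved", "ambiguous", "unclassifiable", ...
    origin_call: str  # label or "unresolved"
    pedigree: str  # "C1", "C1/C2", "C2", "B", "A", "unassigned"
    conflicts: tuple[str, ...]
    note: str | None = None


def _pedigree(origin: str, species: str, conflicts: tuple[str, ...], pedigree_map: str) -> str:
    if conflicts:
        return "unassigned"
    if origin == "Chinese mainland":
        if species == "A. sinensis":
            return "C1" if pedigree_map == "abstract" else "C1/C2"
        if species.startswith("unresolved"):
            return "C1/C2"
        return "unassigned"
    if origin == "Indonesia":
        return "B"
    if origin == "Indochina":
        return "A"
    return "unassigned"


def classify_sample(
    matk_query: str,
    trnlf_query: str | None = None,
    key: DiagnosticKey | None = None,
    sample_id: str = "query",
    pedigree_map: str = "results",
) -> ClassificationResult:
    """Assign species / origin / pedigree to one sample.

    Rules are evaluated in tier order: the two matK species rules jointly,
    the matK origin rule, then the optional trnL-trnF origin refinement.
    Indeterminate positions (deleted in the query) contribute no evidence;
    a sample indeterminate at every key position is "unclassifiable".
    """
    if pedigree_map not in PEDIGREE_MAPS:
        raise ValueError(f"pedigree_map must be one of {PEDIGREE_MAPS}")
    key = default_key() if key is None or isinstance(key, _LazyKey) else key
    note_refine: str | None = None
    maps: dict[str, dict[int, str]] = {}
    try:
        maps["matK"] = map_to_reference(matk_query, "matK")
    except MappingError as err:
        return ClassificationResult(
            sample_id=sample_id, evidence=(), species_call="unclassifiable",
            origin_call="unresolved", pedigree="unassigned", conflicts=(),
            note=f"matK mapping failed: {err}",
        )
    if trnlf_query is not None:
        try:
            maps["trnL-trnF"] = map_to_reference(trnlf_query, "trnL-trnF")
        except MappingError as err:
            trnlf_query = None
            note_refine = f"trnL-trnF mapping failed: {err}"

    evidence: list[dict] = []
    conflicts: list[str] = []

    def observe(rule: KeyRule) -> bool | None:
        obs = maps.get(rule.marker, {}).get(rule.position)
        match = None if obs is None else (obs == rule.state)
        evidence.append(
            {
                "marker": rule.marker,
                "position": rule.position,
                "expected": rule.state,
                "observed": obs or "indeterminate",
                "tier": rule.tier,
                "label": rule.label,
                "match": match,
            }
        )
        return match

    # species tier: both matK rules must agree
    species_rules = key.tier("species", "matK")
    sp_matches = [observe(r) for r in species_rules]
    observed_matches = [m for m in sp_matches if m is not None]
    if not observed_matches:
        species = "unresolved"
    elif all(observed_matches) and len(observed_matches) == len(sp_matches):
        species = species_rules[0].label
    elif all(observed_matches):
        species = "unresolved"  # partial (indeterminate) corroboration
    elif any(observed_matches):
        species = "ambiguous"
        conflicts.append(
            "species-tier matK rules disagree: "
            + ", ".join(
                f"+{r.position}{'=' if m else '!='}{r.state}"
                for r, m in zip(species_rules, sp_matches)
                if m is not None
            )
        )
    else:
        species = "unresolved"

    # origin tier (matK +249)
    origin = "unresolved"
    for rule in key.tier("origin", "matK"):
        if observe(rule):
            origin = rule.label
    if origin == "Chinese mainland" and species == "unresolved":
        species = UNRESOLVED_CHINESE

    # trnL-trnF refinement: origin only, never overrides a species call
    if trnlf_query is not None:
        refined = [r.label for r in key.tier("refine", "trnL-trnF") if observe(r)]
        if len(refined) == 1:
            if origin == "unresolved":
                origin = refined[0]
            elif refined[0] != origin:
                conflicts.append(
                    f"trnL-trnF refinement ({refined[0]}) conflicts with matK origin ({origin})"
                )
        elif len(refined) > 1:
            conflicts.append(f"multiple trnL-trnF clusters match: {refined}")

    if all(e["match"] is None for e in evidence):
        return ClassificationResult(
            sample_id=sample_id, evidence=tuple(evidence),
            species_call="unclassifiable", origin_call="unresolved",
            pedigree="unassigned", conflicts=tuple(conflicts),
            note="indeterminate at all key positions",
        )
    pedigree = _pedigree(origin, species, tuple(conflicts), pedigree_map)
    if species == "ambiguous":
        pedigree = "unassigned"
    return ClassificationResult(
        sample_id=sample_id,
        evidence=tuple(evidence),
        species_call=species,
        origin_call=origin,
        pedigree=pedigree,
        conflicts=tuple(conflicts),
        note=note_refine,
    )


def classify_panel(
    panel: list[tuple[SampleMetadata, str, str | None]],
    key: DiagnosticKey | None = None,
    pedigree_map: str = "results",
) -> tuple[list[ClassificationResult], pd.DataFrame, dict]:
    """Classify a panel; per-sample failures never abort the run.

    Returns (results, per-sample table, aggregate dict with counts and the
    Chinese-origin fraction).
    """
    if not panel:
        raise ValueError("panel is empty")
    results: list[ClassificationResult] = []
    for meta, matk, trnl in panel:
        try:
            results.append(
                classify_sample(matk, trnl, key=key, sample_id=meta.id, pedigree_map=pedigree_map)
            )
        except Exception as err:  # noqa: BLE001 — isolate per-sample failures
            results.append(
                ClassificationResult(
                    sample_id=meta.id, evidence=(), species_call="unclassifiable",
                    origin_call="unresolved", pedigree="unassigned", conflicts=(),
                    note=f"error: {err}",
                )
            )
    table = pd.DataFrame(
        [
            {
                "id": r.sample_id,
                "species": r.species_call,
                "origin": r.origin_call,
                "pedigree": r.pedigree,
                "n_conflicts": len(r.conflicts),
                "note": r.note or "",
            }
            for r in results
        ]
    )
    n = len(results)
    n_chinese = int((table["origin"] == "Chinese mainland").sum())
    aggregate = {
        "n_samples": n,
        "by_origin": table["origin"].value_counts().to_dict(),
        "by_pedigree": table["pedigree"].value_counts().to_dict(),
        "n_chinese": n_chinese,
        "chinese_fraction": n_chinese / n,
    }
    return results, table, aggregate
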