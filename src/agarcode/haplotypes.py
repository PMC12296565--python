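"""Haplotype collapsing and segregating-site (SNP%) statistics.

Within a group (usually one species), columns containing a gap, N or any
ambiguity code in *any* group member are excluded from the comparison mask
(DnaSP-style "sites with gaps/missing excluded"). Sequences identical over
the mask collapse into one haplotype; segregating sites are mask columns
with two or more distinct bases in the group, and

    SNP% = 100 * segregating_sites / masked_alignment_length.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .alignio import LabeledAlignment
from .distances import encode


@dataclasses.dataclass(frozen=True)
class Haplotype:
    name: str
    sequence: str  # over mask columns
    members: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclasses.dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes of one group plus its SNP statistics."""

    marker: str
    group: str
    haplotypes: tuple[Haplotype, ...]
    mask_columns: tuple[int, ...]  # 0-based alignment columns used
    n_sequences: int
    s_sites: int

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def aligned_length_used(self) -> int:
        return len(self.mask_columns)

    @property
    def snp_percent(self) -> float:
        if self.aligned_length_used == 0:
            return 0.0
        return 100.0 * self.s_sites / self.aligned_length_used


def _group_alignment(aln: LabeledAlignment, group: str) -> LabeledAlignment:
    return aln if group == "all" else aln.by_species(group)


def _mask_and_codes(sub: LabeledAlignment) -> tuple[np.ndarray, np.ndarray]:
    codes = np.stack([encode(s) for s in sub.seqs])
    mask = (codes < 4).all(axis=0)
    return codes, mask


def collapse_haplotypes(aln: LabeledAlignment, group: str = "all", marker: str | None = None) -> HaplotypeTable:
    """Collapse one group's sequences into haplotypes.

    Haplotype names are ``<group>_NN`` (01-based), assigned by descending
    member count, ties broken by first occurrence in input order.
    """
    sub = _group_alignment(aln, group)
    codes, mask = _mask_and_codes(sub)
    cols = np.flatnonzero(mask)
    keys = ["".join(sub.seqs[i][c] for c in cols) for i in range(sub.n)]
    members: dict[str, list[str]] = {}
    for rid, key in zip(sub.ids, keys):
        members.setdefault(key, []).append(rid)
    order = sorted(members, key=lambda k: (-len(members[k]), keys.index(k)))
    label = group if group != "all" else "Hap"
    haps = tuple(
        Haplotype(name=f"{label}_{i + 1:02d}", sequence=key, members=tuple(members[key]))
        for i, key in enumerate(order)
    )
    masked = codes[:, mask]
    s_sites = int(((masked != masked[0]).any(axis=0)).sum()) if sub.n > 1 else 0
    return HaplotypeTable(
        marker=marker or aln.marker,
        group=group,
        haplotypes=haps,
        mask_columns=tuple(int(c) for c in cols),
        n_sequences=sub.n,
        s_sites=s_sites,
    )


def snp_statistics(aln: LabeledAlignment, group: str = "all") -> dict:
    """Segregating sites and SNP% for one group.

    A single-sequence group yields ``s_sites = 0`` with an explanatory note.
    """
    table = collapse_haplotypes(aln, group)
    note = None
    if table.n_sequences < 2:
        note = "single-sequence group: no segregating sites computable"
    return {
        "s_sites": table.s_sites,
        "aligned_length_used": table.aligned_length_used,
        "snp_percent": table.snp_percent,
        "note": note,
    }


def haplotype_summary(alns: dict[str, LabeledAlignment]) -> pd.DataFrame:
    """Species-by-marker summary table (sequence count, haplotypes, SNP%).

    One row per species per marker; species absent from a marker simply
    contribute no row for it.
    """
    if not alns:
        raise ValueError("need at least one marker alignment")
    rows = []
    for marker, aln in alns.items():
        for sp in sorted(aln.species_set()):
            t = collapse_haplotypes(aln, sp, marker=marker)
            rows.append(
                {
                    "marker": marker,
                    "species": sp,
                    "n_sequences": t.n_sequences,
                    "n_haplotypes": t.n_haplotypes,
                    "snp_percent": round(t.snp_percent, 2),
                }
            )
    return pd.DataFrame(rows)


def write_haplotype_fasta(table: HaplotypeTable, path: str | Path) -> Path:
    """Write representative sequences with counts in the headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for hap in table.haplotypes:
            fh.write(f">{hap.name}|n={hap.count}|members={','.join(hap.members)}\n")
            fh.write(hap.sequence + "\n")
    return path
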