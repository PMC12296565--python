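"""Regenerate the bundled synthetic reference alignments and key file.

The reference alignments define the 1-based "+N" coordinate frame used by
the diagnostic key. They are synthetic stand-ins generated from a fixed
seed, with the key's diagnostic states planted at their loci; re-running
this script reproduces them byte-for-byte.

Usage: python scripts/make_reference_fixtures.py
"""

from __future__ import annotations

from pathlib import Path

from agarcode.alignio import write_fasta
from agarcode.synthgen import PlantedSite, SpeciesSpec, SynthConfig, generate_alignment

DATA = Path(__file__).resolve().parent.parent / "src" / "agarcode" / "data"

CHINESE = ("A. sinensis", "A. yunnanensis")
INDOCHINA = ("A. crassna", "A. rugosa", "A. cumingiana")
MALESIAN = ("A. malaccensis", "A. beccariana", "A. microcarpa", "A. hirta")

SPECIES = [
    SpeciesSpec("A. sinensis", 3, origin="Chinese mainland"),
    SpeciesSpec("A. yunnanensis", 3, origin="Chinese mainland"),
    SpeciesSpec("A. crassna", 3, origin="Indochina"),
    SpeciesSpec("A. rugosa", 3, origin="Indochina"),
    SpeciesSpec("A. cumingiana", 3, origin="Indonesia"),
    SpeciesSpec("A. malaccensis", 3, origin="Indonesia"),
    SpeciesSpec("A. beccariana", 3, origin="Indonesia"),
    SpeciesSpec("A. microcarpa", 3, origin="Indonesia"),
    SpeciesSpec("A. hirta", 3, origin="Malaysia"),
]

MATK = SynthConfig(
    marker="matK",
    length=750,
    species=tuple(SPECIES),
    theta_intra=0.001,
    theta_inter=0.015,
    kappa=2.0,
    diagnostics=(
        PlantedSite(249, CHINESE, "C"),
        PlantedSite(435, ("A. sinensis",), "G"),
        PlantedSite(684, ("A. sinensis",), "T"),
        # auxiliary clustering loci
        PlantedSite(58, CHINESE, "A"),
        PlantedSite(124, CHINESE, "G"),
        PlantedSite(232, MALESIAN, "C"),
        PlantedSite(261, MALESIAN, "T"),
        PlantedSite(338, INDOCHINA, "G"),
        PlantedSite(373, INDOCHINA, "A"),
        PlantedSite(559, INDOCHINA, "C"),
    ),
    seed=42,
)

TRNL = SynthConfig(
    marker="trnL-trnF",
    length=450,
    species=tuple(SPECIES),
    theta_intra=0.002,
    theta_inter=0.03,
    kappa=2.0,
    diagnostics=(
        PlantedSite(173, CHINESE, "G"),
        PlantedSite(183, ("A. cumingiana",) + MALESIAN, "T"),
        PlantedSite(200, ("A. crassna", "A. rugosa"), "A"),
    ),
    polyt=((32, 44, (8, 13)), (323, 343, (12, 21))),
    seed=43,
)

KEY_TSV = """\
# Diagnostic key: marker, 1-based reference column, expected state, tier, label.
# trnL-trnF refinement states and the auxiliary cluster loci follow the
# synthetic reference-alignment convention bundled with the package.
marker\tposition\tstate\ttier\tlabel
matK\t249\tC\torigin\tChinese mainland
matK\t435\tG\tspecies\tA. sinensis
matK\t684\tT\tspecies\tA. sinensis
trnL-trnF\t173\tG\trefine\tChinese mainland
trnL-trnF\t183\tT\trefine\tIndonesia
trnL-trnF\t200\tA\trefine\tIndochina
matK\t58\tA\tcluster\tChinese cluster
matK\t124\tG\tcluster\tChinese cluster
matK\t232\tC\tcluster\tMalesian cluster
matK\t261\tT\tcluster\tMalesian cluster
matK\t338\tG\tcluster\tIndochina cluster
matK\t373\tA\tcluster\tIndochina cluster
matK\t559\tC\tcluster\tIndochina cluster
"""


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    matk_aln, _ = generate_alignment(MATK)
    write_fasta(matk_aln, DATA / "matk_reference_synthetic.fasta")
    trnl_aln, _ = generate_alignment(TRNL)
    write_fasta(trnl_aln, DATA / "trnl_trnf_reference_synthetic.fasta")
    (DATA / "diagnostic_key.tsv").write_text(KEY_TSV)
    print(f"wrote fixtures to {DATA}")


if __name__ == "__main__":
    main()
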