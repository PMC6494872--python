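"""Published per-sample results for the Masłomęcz Iron Age cohort (Mas-VBIA).

The cohort comprises 27 individuals from a Wielbark-culture cemetery near
Masłomęcz, eastern Poland (2nd-4th century AD).  Haplogroup assignments,
anthropological sex and genetic sex calls are published study results and
serve as analysis inputs here; the underlying consensus sequences are
deposited in GenBank (MH492638-MH492664) and are not bundled.
"""

from __future__ import annotations

from .io import Era, Individual, Sex, TransectDataset

#: (sample_id, haplogroup, anthropological sex, genetic sex) per individual.
#: Genetic sex "" means the sample had too few sex-chromosome reads to call.
MASLOMECZ_TABLE: tuple[tuple[str, str, str, str], ...] = (
    ("PCA0088", "U3a1a", "M", ""),
    ("PCA0089", "J1c3", "F", "F"),
    ("PCA0090", "U3a1a", "", "F"),
    ("PCA0091", "U5a1b3", "", "M"),
    ("PCA0092", "H16", "F", "F"),
    ("PCA0093", "T1a9", "M", "M"),
    ("PCA0094", "HV0f", "F", "F"),
    ("PCA0095", "H11a1", "", ""),
    ("PCA0096", "U4c1", "", ""),
    ("PCA0097", "T2a1a", "", ""),
    ("PCA0098", "H1e2", "", ""),
    ("PCA0099", "H1cg", "", "F"),
    ("PCA0100", "HV0f", "M", "M"),
    ("PCA0101", "U5a2b3", "", ""),
    ("PCA0102", "K1c1", "M", "M"),
    ("PCA0103", "H2a1a", "F", "F"),
    ("PCA0104", "H1a3", "", ""),
    ("PCA0105", "U5a2a1", "", "F"),
    ("PCA0106", "T2b", "", ""),
    ("PCA0107", "U5a1b1e", "", ""),
    ("PCA0108", "T2b23", "", ""),
    ("PCA0109", "K1a27", "", "F"),
    ("PCA0110", "H5e1b", "M", "M"),
    ("PCA0111", "N1a1a1a2", "F", "F"),
    ("PCA0112", "T2b2b", "", ""),
    ("PCA0113", "V", "", ""),
    ("PCA0114", "H7a1a", "", ""),
)

#: The two whole-mtDNA-identical pairs found among the 27 individuals.
MASLOMECZ_DUPLICATE_PAIRS: tuple[tuple[str, str], ...] = (
    ("PCA0088", "PCA0090"),
    ("PCA0094", "PCA0100"),
)

MASLOMECZ_POPULATION = "Mas-VBIA"


def maslomecz_dataset() -> TransectDataset:
    """The 27-individual cohort as a sequence-free TransectDataset."""
    individuals = [
        Individual(
            sample_id=sid,
            population=MASLOMECZ_POPULATION,
            era=Era.IA,
            haplogroup_label=hg,
            anthropological_sex=Sex(anthro) if anthro else Sex.UNKNOWN,
        )
        for sid, hg, anthro, _genetic in MASLOMECZ_TABLE
    ]
    return TransectDataset(
        individuals=individuals,
        populations={MASLOMECZ_POPULATION: Era.IA},
        provenance="Masłomęcz Iron Age cemetery cohort, published haplogroup table",
    )
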