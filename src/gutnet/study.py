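"""Reference study design: eight sympatric tephritid fruit-fly species of
Reunion Island, each sampled once in the laboratory and once in the field.

The sixteen samples and their host factors (genus-level phylogeny group,
tribe, host-range specialization, sampling environment) are fixed facts of
the study system and are used both by the synthetic generator (to mirror the
design) and by the ordination tests (as printed inputs).  Species codes:

====  ==========================  =============  ==========
code  species                     tribe          host range
====  ==========================  =============  ==========
BD    Bactrocera dorsalis         Dacinae        generalist
BZ    Bactrocera zonata           Dacinae        generalist
CC    Ceratitis capitata          Ceratitinae    generalist
CQ    Ceratitis quilicii          Ceratitinae    generalist
DC    Dacus ciliatus              Dacinae        Cucurbitaceae
DD    Dacus demmerezi             Dacinae        Cucurbitaceae
NC    Neoceratitis cyanescens     Ceratitinae    Solanaceae
ZC    Zeugodacus cucurbitae       Dacinae        Cucurbitaceae
====  ==========================  =============  ==========

Phylogeny groups collapse the five fly genera into four: *Neoceratitis*,
*Ceratitis*, *Dacus*, and *Bactrocera* together with its close relative
*Zeugodacus*.
"""

from __future__ import annotations

import pandas as pd

from gutnet.io import SampleMetadata

SPECIES_PHYLOGENY = {
    "BD": "Bactrocera+Zeugodacus",
    "BZ": "Bactrocera+Zeugodacus",
    "CC": "Ceratitis",
    "CQ": "Ceratitis",
    "DC": "Dacus",
    "DD": "Dacus",
    "NC": "Neoceratitis",
    "ZC": "Bactrocera+Zeugodacus",
}

SPECIES_TRIBE = {
    "BD": "Dacinae",
    "BZ": "Dacinae",
    "CC": "Ceratitinae",
    "CQ": "Ceratitinae",
    "DC": "Dacinae",
    "DD": "Dacinae",
    "NC": "Ceratitinae",
    "ZC": "Dacinae",
}

SPECIES_SPECIALIZATION = {
    "BD": "generalist",
    "BZ": "generalist",
    "CC": "generalist",
    "CQ": "generalist",
    "DC": "Cucurbitaceae",
    "DD": "Cucurbitaceae",
    "NC": "Solanaceae",
    "ZC": "Cucurbitaceae",
}

ENV_SUFFIX = {"laboratory": "Lab", "field": "Nat"}


def sample_id(species: str, environment: str) -> str:
    return f"{species}-{ENV_SUFFIX[environment]}"


def study_metadata() -> SampleMetadata:
    """The 16-sample design: 8 species x {laboratory, field}."""
    rows = []
    for species in sorted(SPECIES_PHYLOGENY):
        for environment in ("laboratory", "field"):
            rows.append(
                {
                    "sample_id": sample_id(species, environment),
                    "species": species,
                    "phylogeny_group": SPECIES_PHYLOGENY[species],
                    "tribe": SPECIES_TRIBE[species],
                    "specialization": SPECIES_SPECIALIZATION[species],
                    "environment": environment,
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(df)


def weighted_matrix_sample_groups() -> pd.Series:
    """The three sample groups the latent block model finds on the full
    read-count matrix: field *Bactrocera*/*Zeugodacus* samples; all *Dacus*
    samples; and the remainder (all Ceratitinae plus laboratory
    *Bactrocera*/*Zeugodacus*)."""
    meta = study_metadata().table
    groups = {}
    for sid, row in meta.iterrows():
        if row["phylogeny_group"] == "Bactrocera+Zeugodacus" and row["environment"] == "field":
            groups[sid] = "field-BZ"
        elif row["phylogeny_group"] == "Dacus":
            groups[sid] = "Dacus"
        else:
            groups[sid] = "rest"
    return pd.Series(groups, name="group")
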