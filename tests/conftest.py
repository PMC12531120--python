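"""Shared fixtures: scaled-down synthetic organs and tiny hand-built inputs."""

from dataclasses import replace

import pandas as pd
import pytest

from fieldmap.io_formats import FieldMap, MutationTable
from fieldmap.synthetic_organ import (
    OmicsPlatformConfig,
    OrganConfig,
    generate_organ,
)


def small_config(**overrides) -> OrganConfig:
    """A fast organ: same spatial structure, far fewer alpha mutations."""
    cfg = OrganConfig(
        n_alpha=(300, 10, 8),
        n_beta=(51, 1, 2),
        n_gamma=(150, 2, 4),
        shared_loci=(5, 1, 2),
        rna=OmicsPlatformConfig(
            n_analytes=400, n_up=40, n_down=60,
            wave1_up=10, wave1_down=10, wave2_up=3, wave2_down=5,
            n_transient=20, missing_fraction=0.0,
        ),
        protein=OmicsPlatformConfig(
            n_analytes=200, n_up=30, n_down=30,
            wave1_up=10, wave1_down=10, wave2_up=5, wave2_down=5,
            n_transient=10, missing_fraction=0.08,
        ),
        metabolite=OmicsPlatformConfig(
            n_analytes=50, n_up=8, n_down=8,
            wave1_up=3, wave1_down=3, wave2_up=1, wave2_down=1,
            n_transient=2, missing_fraction=0.05,
        ),
        concordant_proteins=30,
    )
    return replace(cfg, **overrides) if overrides else cfg


@pytest.fixture(scope="session")
def small_organ():
    return generate_organ(small_config(), seed=11)


@pytest.fixture(scope="session")
def default_organ_mutations():
    """The full-size organ (mutations only), shared across tests."""
    return generate_organ(OrganConfig(), seed=1, include_omics=False)


@pytest.fixture()
def tiny_field_map() -> FieldMap:
    table = pd.DataFrame(
        {
            "row": [0, 0, 1, 1],
            "col": [0, 1, 0, 1],
            "grade": ["NU", "LGIN", "HGIN", "UC"],
        },
        index=pd.Index(["A1", "A2", "B1", "B2"], name="field_id"),
    )
    return FieldMap(table)


def make_mutation_table(vaf: pd.DataFrame, contexts=None, mtypes=None,
                        silent=None) -> MutationTable:
    """Hand-build a MutationTable around a VAF frame."""
    n = len(vaf)
    ids = list(vaf.index)
    meta = pd.DataFrame(
        {
            "gene": [f"GENE{i}" for i in range(n)],
            "locus": [f"L{i}" for i in range(n)],
            "mtype": mtypes if mtypes is not None else ["SNV"] * n,
            "context": contexts if contexts is not None else ["A[C>T]G"] * n,
            "silent": silent if silent is not None else [False] * n,
        },
        index=pd.Index(ids, name="mutation_id"),
    )
    snv = meta["mtype"] == "SNV"
    meta["substitution"] = ""
    meta.loc[snv, "substitution"] = meta.loc[snv, "context"].str.slice(2, 5)
    meta.loc[~snv, "context"] = "."
    return MutationTable(meta, vaf)
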