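import numpy as np
import pytest

from duckscan.variant_io import AlleleCountTable, VariantTable


def act_from_counts(c_alt, n_called, scaffold="s1", positions=None, population="pop",
                    n_het=None, n_ind=None):
    """AlleleCountTable from plain allele-count vectors (no het information)."""
    c_alt = np.asarray(c_alt, dtype=np.int64)
    n_called = np.asarray(n_called, dtype=np.int64)
    k = c_alt.size
    if positions is None:
        positions = np.arange(k) * 10 + 5
    return AlleleCountTable(
        population=population,
        scaffold=np.array([scaffold] * k, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        c_alt=c_alt,
        n_called=n_called,
        n_het=np.zeros(k, np.int64) if n_het is None else np.asarray(n_het),
        n_ind=(n_called // 2) if n_ind is None else np.asarray(n_ind),
    )


def act_from_genotypes(geno, scaffold="s1", positions=None, population="pop"):
    """AlleleCountTable from an (n_sites, n_ind, 2) genotype array (no missing)."""
    geno = np.asarray(geno)
    k = geno.shape[0]
    if positions is None:
        positions = np.arange(k) * 10 + 5
    return AlleleCountTable(
        population=population,
        scaffold=np.array([scaffold] * k, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        c_alt=(geno == 1).sum(axis=(1, 2)),
        n_called=np.full(k, geno.shape[1] * 2),
        n_het=(geno[:, :, 0] != geno[:, :, 1]).sum(axis=1),
        n_ind=np.full(k, geno.shape[1]),
    )


@pytest.fixture
def tiny_variant_table():
    """3 sites x 4 diploids (2 per population), no missing data."""
    geno = np.array(
        [
            [[0, 0], [0, 1], [1, 1], [1, 1]],
            [[0, 1], [0, 1], [0, 0], [0, 1]],
            [[1, 1], [1, 1], [0, 0], [0, 0]],
        ],
        dtype=np.int8,
    )
    return VariantTable(
        scaffold=np.array(["s1"] * 3, dtype=object),
        pos=np.array([100, 200, 300]),
        ref=np.array(["A", "C", "G"], dtype=object),
        alt=np.array(["T", "G", "A"], dtype=object),
        genotypes=geno,
        samples=["BD_1", "BD_2", "CD_1", "CD_2"],
        populations={"BD_1": "BD", "BD_2": "BD", "CD_1": "CD", "CD_2": "CD"},
    )
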