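import numpy as np
import pytest

import vcqtl as v


@pytest.fixture(scope="session")
def trio_pedigree():
    """Two founder couples, two F1, four F2 full sibs."""
    recs = [
        ("S1", None, None, "male", "F0", "A"),
        ("D1", None, None, "female", "F0", "B"),
        ("S2", None, None, "male", "F0", "A"),
        ("D2", None, None, "female", "F0", "B"),
        ("B1", "S1", "D1", "male", "F1", None),
        ("W1", "S2", "D2", "female", "F1", None),
        ("X1", "B1", "W1", "female", "F2", None),
        ("X2", "B1", "W1", "castrate", "F2", None),
        ("X3", "B1", "W1", "female", "F2", None),
        ("X4", "B1", "W1", "female", "F2", None),
    ]
    return v.Pedigree(recs)


@pytest.fixture(scope="session")
def small_design():
    """Small but non-trivial intercross reused across modules."""
    return v.SimulationDesign(
        n_f0_sires=4,
        n_f0_dams=6,
        n_f1_boars=4,
        n_f1_sows=12,
        sows_per_boar=(3, 3),
        litters_per_sow=(1, 2),
        n_f2=160,
        n_groups=1,
        markers_per_group=(5,),
        marker_spacing_cm=15.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    gmap = v.make_map(small_design)
    ped = v.make_pedigree(small_design, seed=11)
    geno, truth = v.drop_genomes(ped, gmap, small_design, seed=12)
    return small_design, gmap, ped, geno, truth


def fully_informative_genotypes(ped, gmap, seed=0):
    """Genotypes where every founder carries two globally unique alleles:
    descent is fully identified at every marker."""
    import vcqtl._descent as d

    rng = np.random.default_rng(seed)
    n_loci = sum(len(g.markers) for g in gmap.groups)
    data = np.zeros((ped.n, n_loci, 2), dtype=np.int32)
    names = []
    truth_S = {}
    col = 0
    for g in gmap.groups:
        L = len(g.markers)
        S = rng.integers(0, 2, size=(L, ped.n_meioses)).astype(np.uint8)
        truth_S[g.name] = S
        fp = np.zeros(ped.n, dtype=np.int64)
        fm = np.zeros(ped.n, dtype=np.int64)
        for l in range(L):
            d.slots_at(ped.sire_idx, ped.dam_idx, ped.founder_ord, ped.nonfounder_ord, S[l], fp, fm)
            for i in range(ped.n):
                data[i, col, 0] = fp[i] + 1
                data[i, col, 1] = fm[i] + 1
            col += 1
        names.extend(g.markers)
    return v.GenotypeTable(ped.ids, names, data), truth_S
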