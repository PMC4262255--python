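import numpy as np
import pandas as pd
import pytest

import ssbr


def make_random_pedigree(rng, n, p_parent=0.7):
    """Random valid pedigree of n individuals; parents drawn among earlier
    individuals (so ordering is trivially valid before shuffling)."""
    records = []
    for i in range(n):
        sire = dam = "0"
        if i >= 2 and rng.random() < p_parent:
            sire = str(int(rng.integers(0, i)) + 1)
            dam_i = int(rng.integers(0, i)) + 1
            dam = str(dam_i) if str(dam_i) != sire else "0"
        records.append((str(i + 1), sire, dam))
    return records


def make_random_dataset(rng, n=30, m=8, frac_genotyped=0.5):
    """Random pedigree + genotypes on a random subset + phenotypes."""
    records = make_random_pedigree(rng, n)
    ids = [r[0] for r in records]
    k = max(2, int(frac_genotyped * n))
    genotyped = list(rng.choice(ids, size=k, replace=False))
    M2 = rng.integers(0, 3, size=(k, m)).astype(float)
    md = ssbr.MarkerData([f"m{j + 1}" for j in range(m)], M2)
    phen_ids = [i for i in ids if rng.random() < 0.8]
    if len(phen_ids) < 3:
        phen_ids = ids[:3]
    phen = pd.DataFrame({"id": phen_ids,
                         "y": rng.normal(size=len(phen_ids))})
    data = ssbr.SSBRData.from_tables(records, genotyped, md, phen)
    return data


@pytest.fixture(scope="session")
def example():
    """The 6-animal worked example with every derived object precomputed."""
    ped, md, phen, cfg = ssbr.load_worked_example()
    rel = ssbr.build_A_inverse(ped)
    cov = ssbr.impute_markers(rel, md)
    spec = cfg.model_spec()
    design = ssbr.build_W(cov, md, ped, phen)
    mem = ssbr.build_mme_mem(design, rel, spec, md.marker_ids)
    sol = ssbr.solve_blup(mem)
    bv = ssbr.predict_bv(sol, cov, md, mem)
    return {
        "ped": ped, "md": md, "phen": phen, "cfg": cfg, "rel": rel,
        "cov": cov, "spec": spec, "design": design, "mem": mem,
        "sol": sol, "bv": bv,
    }
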