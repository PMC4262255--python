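"""Synthetic halfsib study for exercising single-step prediction.

The generator emulates a paternal halfsib design: unrelated sires each mated
to a set of unrelated dams, one offspring per dam. Founder haplotypes are
drawn per locus in Hardy-Weinberg proportions (linkage equilibrium) at
frequencies sampled from a uniform law; markers sit on a genetic map
(default: one 1-Morgan chromosome) and offspring gametes arise by gene
dropping with Haldane recombination between adjacent loci, so linked markers
co-segregate within families the way they do in a real mapping population.
A random subset of the markers are QTL. Their effect dispersion is scaled so
the deviation part of the founder genetic variance hits the heritability
target against a unit environmental-variance baseline; ``mu_alpha`` is then
added in trait units (a non-null effect mean shifts breeding values through
total dosage, which is what breaks uncentered models without mu_g), and the
environmental variance is set from the realized total genetic variance so
the heritability is exact. Phenotypes (true BV plus normal noise) are
recorded for all offspring and for the first ``n_dams_phenotyped`` dams;
only offspring are genotyped.

``evaluate_accuracy`` refits the data by single-step BLUP under three model
variants -- centered covariates (CC), uncentered covariates with the mu_g
fixed effect (CN+mu_g), and uncentered without mu_g (CN) -- and reports the
correlation between predicted and true breeding values separately for the
non-genotyped (sires and dams) and genotyped (offspring) animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import SingleStepBLUP, SSBRData
from .imputation import MarkerData

__all__ = ["SimConfig", "SimOutput", "simulate_population", "evaluate_accuracy"]

VARIANTS = ("CC", "CN_mug", "CN")


@dataclass
class SimConfig:
    """Study design for the halfsib simulation."""

    n_sires: int = 20
    dams_per_sire: int = 20
    n_qtl: int = 50
    n_markers: int = 100
    h2: float = 0.5
    mu_alpha: float = 0.0
    founder_freq_law: tuple[float, float] = (0.1, 0.9)
    n_dams_phenotyped: int = 210
    n_chrom: int = 1
    chrom_length: float = 1.0     # Morgans per chromosome
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        if self.n_chrom < 1 or self.chrom_length <= 0:
            raise ValueError("need at least one chromosome of positive length")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        lo, hi = self.founder_freq_law
        if not (0 < lo <= hi < 1):
            raise ValueError("founder frequencies must lie within (0, 1)")
        if self.n_dams_phenotyped > self.n_sires * self.dams_per_sire:
            raise ValueError("more phenotyped dams than dams")


@dataclass
class SimOutput:
    """Simulated pedigree, genotypes (offspring only), phenotypes and truth."""

    pedigree_records: list[tuple[str, str, str]]
    genotype_ids: list[str]
    markers: MarkerData
    phenotypes: pd.DataFrame
    truth: pd.DataFrame               # id, true_bv, genotyped
    qtl: pd.DataFrame                 # marker_id, effect
    config: SimConfig
    var_e: float = field(default=0.0)
    var_g: float = field(default=0.0)  # realized founder genetic variance
    parent_freqs: np.ndarray | None = None  # realized founder allele freqs
    founder_doses: dict | None = None       # {"sire": array, "dam": array, "sire_of": array}

    def data(self) -> SSBRData:
        return SSBRData.from_tables(
            self.pedigree_records, self.genotype_ids, self.markers, self.phenotypes
        )

    def write(self, out_dir) -> dict[str, Path]:
        from .io import write_genotypes

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pedigree": out_dir / "pedigree.txt",
            "genotypes": out_dir / "genotypes.txt",
            "phenotypes": out_dir / "phenotypes.txt",
            "truth": out_dir / "truth.tsv",
        }
        with open(paths["pedigree"], "w") as fh:
            fh.write("id,sire,dam\n")
            for ind, s, d in self.pedigree_records:
                fh.write(f"{ind},{s},{d}\n")
        write_genotypes(paths["genotypes"], self.genotype_ids, self.markers,
                        header_comment=f"halfsib simulation seed={self.config.seed}")
        self.phenotypes.to_csv(paths["phenotypes"], sep=" ", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _recomb_probs(cfg: SimConfig) -> np.ndarray:
    """Recombination probability between adjacent markers (Haldane map
    within a chromosome, free recombination across chromosomes)."""
    m = cfg.n_markers
    pos, chrom = [], []
    base = m // cfg.n_chrom
    for c in range(cfg.n_chrom):
        k = base + (1 if c < m % cfg.n_chrom else 0)
        pos.extend(np.linspace(0.0, cfg.chrom_length, k))
        chrom.extend([c] * k)
    pos, chrom = np.asarray(pos), np.asarray(chrom)
    d = np.diff(pos)
    same = np.diff(chrom) == 0
    return np.where(same, 0.5 * (1.0 - np.exp(-2.0 * d)), 0.5)


def simulate_population(cfg: SimConfig) -> SimOutput:
    """Simulate the halfsib study; deterministic per ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_markers
    n_dams = cfg.n_sires * cfg.dams_per_sire
    sire_ids = [f"S{i + 1}" for i in range(cfg.n_sires)]
    dam_ids = [f"D{i + 1}" for i in range(n_dams)]
    off_ids = [f"O{i + 1}" for i in range(n_dams)]

    freqs = rng.uniform(*cfg.founder_freq_law, size=m)
    # phased founder haplotypes in linkage equilibrium: shape (n, 2, m)
    sire_h = (rng.random((cfg.n_sires, 2, m)) < freqs).astype(np.int8)
    dam_h = (rng.random((n_dams, 2, m)) < freqs).astype(np.int8)

    rprob = _recomb_probs(cfg)
    cols = np.arange(m)

    def meiosis(hap_pair: np.ndarray) -> np.ndarray:
        """One gamete: walk the map, switching parental strand at
        recombination events."""
        switches = rng.random(m - 1) < rprob
        strand = (rng.integers(0, 2)
                  + np.concatenate([[0], np.cumsum(switches)])) % 2
        return hap_pair[strand, cols]

    # gene dropping: offspring k has sire k // dams_per_sire and dam k
    sire_of = np.repeat(np.arange(cfg.n_sires), cfg.dams_per_sire)
    off_dose = np.empty((n_dams, m))
    for k in range(n_dams):
        off_dose[k] = meiosis(sire_h[sire_of[k]]) + meiosis(dam_h[k])
    sire_dose = sire_h.sum(axis=1).astype(float)
    dam_dose = dam_h.sum(axis=1).astype(float)

    qtl_idx = rng.choice(m, size=cfg.n_qtl, replace=False)
    z = np.zeros(m)
    z[qtl_idx] = rng.normal(0.0, 1.0, size=cfg.n_qtl)

    founder_dose = np.vstack([sire_dose, dam_dose])
    v_disp = float(np.var(founder_dose @ z))
    if v_disp <= 0:
        raise ValueError("zero genetic variance among founders; cannot scale to h2")
    # dispersion part of the founder genetic variance = h2 (unit baseline);
    # mu_alpha then adds in trait units, and var_e tracks the realized total
    effects = z * np.sqrt(cfg.h2 / v_disp)
    effects[qtl_idx] += cfg.mu_alpha
    var_g = float(np.var(founder_dose @ effects))
    var_e = var_g * (1.0 - cfg.h2) / cfg.h2

    all_dose = np.vstack([sire_dose, dam_dose, off_dose])
    all_ids = sire_ids + dam_ids + off_ids
    bv = all_dose @ effects

    phen_ids = dam_ids[: cfg.n_dams_phenotyped] + off_ids
    idx = {i: k for k, i in enumerate(all_ids)}
    rows = [idx[i] for i in phen_ids]
    y = bv[rows] + rng.normal(0.0, np.sqrt(var_e), size=len(rows))

    ped = ([(s, "0", "0") for s in sire_ids]
           + [(d, "0", "0") for d in dam_ids]
           + [(o, sire_ids[sire_of[k]], dam_ids[k]) for k, o in enumerate(off_ids)])
    marker_ids = [f"m{j + 1}" for j in range(m)]
    genotyped = set(off_ids)
    return SimOutput(
        pedigree_records=ped,
        genotype_ids=off_ids,
        markers=MarkerData(marker_ids, off_dose),
        phenotypes=pd.DataFrame({"id": phen_ids, "y": y}),
        truth=pd.DataFrame({
            "id": all_ids,
            "true_bv": bv,
            "genotyped": [i in genotyped for i in all_ids],
        }),
        qtl=pd.DataFrame({"marker_id": [marker_ids[j] for j in qtl_idx],
                          "effect": effects[qtl_idx]}),
        config=cfg,
        var_e=var_e,
        var_g=var_g,
        parent_freqs=founder_dose.mean(axis=0) / 2.0,
        founder_doses={"sire": sire_dose, "dam": dam_dose, "sire_of": sire_of},
    )


def evaluate_accuracy(sim: SimOutput, model_variant: str,
                      data: SSBRData | None = None) -> tuple[float, float]:
    """Fit single-step BLUP under a model variant; return Pearson correlations
    of predicted vs true BV for (non-genotyped, genotyped) animals.

    Variants: "CC" centered covariates; "CN_mug" uncentered + mu_g fixed
    effect; "CN" uncentered without mu_g. The analysis uses the simulation's
    own realized variance components (founder genetic variance, the matching
    environmental variance, marker variance from the 2*sum(pq) scaling at
    observed frequencies).
    """
    if model_variant not in VARIANTS:
        raise ValueError(f"unknown variant {model_variant!r}; choose from {VARIANTS}")
    if data is None:
        data = sim.data()
    sigma2_g = sim.var_g
    f = data.markers.observed_freqs()
    sum2pq = float(np.sum(2.0 * f * (1.0 - f)))  # monomorphic loci contribute 0
    var_alpha = sigma2_g / sum2pq
    est = SingleStepBLUP(
        formulation="mem",
        var_e=sim.var_e,
        var_alpha=var_alpha,
        var_eps=sigma2_g,
        fit_mu_g=(model_variant == "CN_mug"),
        centering="observed-mean" if model_variant == "CC" else None,
    )
    est.fit(data)
    truth = sim.truth.set_index("id")
    pred = est.bv_.reindex(truth.index)
    out = []
    for flag in (False, True):
        mask = truth["genotyped"].to_numpy() == flag
        p = pred.to_numpy()[mask]
        t = truth["true_bv"].to_numpy()[mask]
        if np.std(p) == 0 or np.std(t) == 0:
            raise ValueError("degenerate predictions; correlation undefined")
        out.append(float(np.corrcoef(p, t)[0, 1]))
    return out[0], out[1]
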