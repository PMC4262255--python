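"""File formats, run configuration and the shipped worked example.

Formats are deliberately plain text:

* pedigree  -- header ``id,sire,dam`` (comma or whitespace delimited),
               missing parent 0 or empty;
* genotypes -- header ``id m1 m2 ...``, then one row per genotyped
               individual with 0/1/2 dosages;
* phenotypes -- header ``id y [fixed-effect columns...]``;
* config    -- flat ``key = value`` lines (var_e, var_alpha/lambda_alpha,
               var_eps/lambda_eps, fit_mu_g, centering, pi, ...).

Every writer emits a ``#``-prefixed comment header carrying the config hash
and seed so any output can be traced back to its run, and every output is
re-parseable by the readers here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .imputation import ImputedCovariates, MarkerData
from .mme import ModelSpec
from .pedigree import Pedigree, read_pedigree

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_imputed",
    "read_config",
    "load_worked_example",
    "write_report",
]


# ---------------------------------------------------------------------------
# readers / writers

def read_genotypes(path) -> tuple[list[str], MarkerData]:
    """Read a dosage file; returns (individual ids in row order, MarkerData)."""
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    if header[0].lower() != "id":
        raise ValueError("genotype file must start with an 'id' header column")
    marker_ids = header[1:]
    ids, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        ids.append(parts[0])
        vals = np.array(parts[1:], dtype=float)
        if len(vals) != len(marker_ids):
            raise ValueError(f"genotype row for {parts[0]!r} has {len(vals)} entries")
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(vals) - {0.0, 1.0, 2.0})
            raise ValueError(f"malformed dosages {bad} for {parts[0]!r}; only 0/1/2 accepted")
        rows.append(vals)
    return ids, MarkerData(marker_ids, np.array(rows).reshape(len(ids), len(marker_ids)))


def write_genotypes(path, ids, md: MarkerData, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("id " + " ".join(md.marker_ids) + "\n")
        for ind, row in zip(ids, md.M2):
            fh.write(ind + " " + " ".join(_fmt(v) for v in row) + "\n")


def _fmt(v: float) -> str:
    return f"{int(v)}" if float(v).is_integer() else f"{v:.6g}"


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"[,\s]+", engine="python", comment="#")
    df.columns = [c.strip() for c in df.columns]
    if "id" not in df.columns or "y" not in df.columns:
        raise ValueError("phenotype file needs 'id' and 'y' columns")
    df["id"] = df["id"].astype(str)
    return df


def write_imputed(path, ped: Pedigree, cov: ImputedCovariates, md: MarkerData,
                  header_comment: str = "") -> None:
    """Write imputed covariates for set-1 animals with a trailing J column."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("id " + " ".join(md.marker_ids) + " J\n")
        for ind, row, j in zip(ped.set1_ids, cov.M1_hat, cov.J1):
            fh.write(ind + " " + " ".join(f"{v:.6g}" for v in row) + f" {j:.6g}\n")


_TRUE = {"1", "true", "yes", "on"}


def read_config(path) -> dict:
    """Flat key = value config; numerics parsed, booleans recognized."""
    out: dict = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#")[0].strip()
            if not ln:
                continue
            if "=" in ln:
                key, val = ln.split("=", 1)
            else:
                key, *rest = ln.split()
                val = " ".join(rest)
            key, val = key.strip(), val.strip()
            if val.lower() in _TRUE or val.lower() in {"0", "false", "no", "off"}:
                out[key] = val.lower() in _TRUE
            else:
                try:
                    out[key] = float(val)
                except ValueError:
                    out[key] = val
    return out


# ---------------------------------------------------------------------------
# the shipped 6-animal worked example

_FIXTURE_PEDIGREE = [
    ("1", "0", "0"), ("2", "0", "0"), ("3", "0", "0"),
    ("4", "1", "2"), ("5", "1", "2"), ("6", "1", "3"),
]
_FIXTURE_GENOTYPED = ["1", "2", "4"]
_FIXTURE_M2 = np.array([
    [1, 2, 1, 1, 0, 0, 1, 2, 1, 0],
    [2, 1, 1, 1, 2, 0, 1, 1, 1, 1],
    [1, 1, 0, 1, 1, 0, 2, 1, 2, 1],
], dtype=float)
_FIXTURE_PHENOTYPES = {"2": 1.25, "3": -0.34, "4": 1.30, "5": 1.27, "6": 0.46}


def load_worked_example() -> tuple[Pedigree, MarkerData, pd.DataFrame, "RunConfig"]:
    """The 6-animal worked example: half-sib pedigree, 10 markers observed on
    individuals 1, 2 and 4, five phenotypes, and the variance-ratio config
    (lambda_alpha = 10/9, lambda_eps = 1/9) under which the published mixed
    model equations and breeding values are reproduced exactly."""
    ped = Pedigree.from_records(
        _FIXTURE_PEDIGREE, _FIXTURE_GENOTYPED, genotyped_order=_FIXTURE_GENOTYPED
    )
    md = MarkerData([f"m{j}" for j in range(1, 11)], _FIXTURE_M2.copy())
    phen = pd.DataFrame(
        {"id": list(_FIXTURE_PHENOTYPES), "y": list(_FIXTURE_PHENOTYPES.values())}
    )
    cfg = RunConfig(
        var_e=1.0, lambda_alpha=10.0 / 9.0, lambda_eps=1.0 / 9.0, fit_mu_g=True
    )
    return ped, md, phen, cfg


# ---------------------------------------------------------------------------
# run configuration and reports

@dataclass
class RunConfig:
    """Everything needed to re-execute a run."""

    pedigree: str | None = None
    genotypes: str | None = None
    phenotypes: str | None = None
    out_dir: str | None = None
    var_e: float = 1.0
    var_alpha: float | None = None
    var_eps: float | None = None
    lambda_alpha: float | None = None
    lambda_eps: float | None = None
    fit_mu_g: bool = True
    centering: str = "none"
    pi: float = 0.0
    method: str = "BayesC"
    n_iter: int = 10000
    burn_in: int | None = None
    thin: int = 1
    formulation: str = "mem"
    seed: int | None = None

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            var_e=self.var_e,
            var_alpha=self.var_alpha,
            var_eps=self.var_eps,
            lambda_alpha=self.lambda_alpha,
            lambda_eps=self.lambda_eps,
            fit_mu_g=self.fit_mu_g,
            pi=self.pi,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_report(results: dict, out_dir) -> list[Path]:
    """Write solution/BV/summary tables as commented TSV.

    ``results`` maps table name -> DataFrame (or Series); a ``config`` entry
    (RunConfig) contributes the provenance header. Returns written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = results.get("config")
    header_lines = []
    if cfg is not None:
        header_lines.append(f"# config_hash={cfg.config_hash()} seed={cfg.seed}")
        header_lines.append("# " + json.dumps(asdict(cfg), default=str))
    written = []
    for name, table in results.items():
        if name == "config":
            continue
        path = out_dir / f"{name}.tsv"
        if isinstance(table, pd.Series):
            table = table.rename_axis("label").reset_index()
        with open(path, "w") as fh:
            for ln in header_lines:
                fh.write(ln + "\n")
            table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        written.append(path)
    if cfg is not None:
        log = out_dir / "run_log.txt"
        with open(log, "w") as fh:
            fh.write(f"config_hash: {cfg.config_hash()}\nseed: {cfg.seed}\n")
            for key, val in asdict(cfg).items():
                fh.write(f"{key}: {val}\n")
            for key in ("pedigree", "genotypes", "phenotypes"):
                p = getattr(cfg, key)
                if p and Path(p).exists():
                    digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:12]
                    fh.write(f"sha256[{key}]: {digest}\n")
        written.append(log)
    return written
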