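"""File readers/writers, run manifests, and the end-to-end pipeline.

Dense matrices are delimited text with a header row of gene ids and a first
column of cell ids; sparse matrices are MatrixMarket (.mtx) with plain-text
row/column id sidecars (``<file>.rownames`` / ``<file>.colnames``).  The
in-memory orientation is always cells x genes; files stored genes x cells
load with ``transpose=True``.  Gene-set collections use the GMT format
(set name, description, then tab-separated gene ids).  Every pipeline run
writes a JSON manifest (config snapshot, input checksums, seed, version) so
that stochastic outputs are reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import DesignSpec, apply_threshold, build_design
from .gsea import GeneSetCollection, bootstrap_fits, run_gsea
from .hurdle import FitSettings, fit_all
from .postfit import cell_scores, deviance_residuals, module_scores
from .shrinkage import shrink_fit
from .synthetic import SimScenario, simulate
from .testing import de_test

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_covariates",
    "read_gmt",
    "write_gmt",
    "RunManifest",
    "pipeline_run",
]


def read_matrix(path: str | Path, transpose: bool = False):
    """Load a dense delimited or MatrixMarket expression matrix.

    Returns ``(values, row_ids, col_ids)`` in cells x genes orientation
    (after applying ``transpose`` if the file is genes x cells).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        m = mmread(path)
        mat = np.asarray(m.toarray() if hasattr(m, "toarray") else m, dtype=float)
        rows = Path(str(path) + ".rownames").read_text().split()
        cols = Path(str(path) + ".colnames").read_text().split()
        if mat.shape != (len(rows), len(cols)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match sidecar ids "
                f"({len(rows)} rows, {len(cols)} cols)"
            )
    else:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValueError(f"duplicate column ids in {path}")
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.isna().any().any():
            raise ValueError(f"missing or non-numeric entries in {path}")
        mat = df.to_numpy(dtype=float)
        rows = [str(r) for r in df.index]
        cols = [str(c) for c in df.columns]
    if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
        raise ValueError(f"duplicate row or column ids in {path}")
    if transpose:
        mat, rows, cols = mat.T, cols, rows
    return mat, list(rows), list(cols)


def write_matrix(path: str | Path, values: np.ndarray, row_ids, col_ids) -> None:
    """Write a dense matrix with ids, or MatrixMarket + sidecars for .mtx."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(path, csr_matrix(values))
        Path(str(path) + ".rownames").write_text("\n".join(map(str, row_ids)) + "\n")
        Path(str(path) + ".colnames").write_text("\n".join(map(str, col_ids)) + "\n")
    else:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        pd.DataFrame(values, index=row_ids, columns=col_ids).to_csv(path, sep=sep)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Per-cell covariate table; the first column is the cell-id key."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate cell ids in covariate table {path}")
    return df


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields")
        name, _desc, *members = fields
        members = [g for g in dict.fromkeys(m.strip() for m in members) if g]
        if not members:
            import warnings

            warnings.warn(f"{path}:{lineno}: empty gene set {name!r} dropped")
            continue
        sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    lines = [
        "\t".join([name, "na", *members]) for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunManifest:
    command: str
    config: dict
    input_checksums: dict
    seed: int | None
    version: str
    started: str
    finished: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def pipeline_run(config: dict, outdir: str | Path) -> dict:
    """Execute fit -> shrink -> test (-> gsea/residuals/scores) from a config.

    Config keys: either ``simulate`` (a SimScenario field mapping) or
    ``matrix``/``covariates`` paths (+ optional ``transpose``); ``formula``
    (list of covariate terms), ``include_cdr`` (default True), ``term`` (the
    tested term), ``threshold``, ``seed``, ``method``, ``fdr_cut``,
    ``logfc_cut``; optional ``gmt`` + ``n_boot`` for GSEA; optional flags
    ``residuals`` and ``scores``.  Writes all result tables and a manifest
    under ``outdir`` and returns the artifact paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    checksums = {}
    seed = int(config.get("seed", 0))

    if "simulate" in config:
        scenario = SimScenario(**{**config["simulate"], "seed": seed})
        assay, covariates, _truth = simulate(scenario)
        write_matrix(outdir / "matrix.csv", assay.values, assay.cell_ids, assay.gene_ids)
        covariates.to_csv(outdir / "covariates.csv")
    else:
        mat, cells, genes = read_matrix(config["matrix"], config.get("transpose", False))
        checksums["matrix"] = _checksum(config["matrix"])
        covariates = read_covariates(config["covariates"])
        checksums["covariates"] = _checksum(config["covariates"])
        covariates = covariates.loc[cells]
        assay = apply_threshold(
            mat, float(config.get("threshold", 0.0)), cells, genes
        )

    terms = list(config.get("formula", [c for c in covariates.columns]))
    spec = DesignSpec(covariates, terms, include_cdr=bool(config.get("include_cdr", True)))
    term = config.get("term", terms[0])
    settings = FitSettings(use_prior=bool(config.get("use_prior", True)))

    results, fit = de_test(
        assay,
        spec,
        term,
        method=config.get("method", "lrt"),
        settings=settings,
        fdr_cut=float(config.get("fdr_cut", 0.01)),
        logfc_cut=float(config.get("logfc_cut", np.log2(1.5))),
    )
    artifacts = {"de": str(outdir / "de_results.csv")}
    results.to_csv(outdir / "de_results.csv", index=False)
    fit.coefficient_table().to_csv(outdir / "coefficients.csv", index=False)
    artifacts["coefficients"] = str(outdir / "coefficients.csv")

    if config.get("gmt"):
        collection = read_gmt(config["gmt"])
        checksums["gmt"] = _checksum(config["gmt"])
        strata = covariates[term].to_numpy() if term in covariates.columns else None
        from .data_model import term_columns

        design = fit.design
        cols = term_columns(design, term)
        gsea_term = term if len(cols) == 1 else design.columns[cols[0]]
        boot = bootstrap_fits(
            assay, design, int(config.get("n_boot", 50)), seed, strata, settings
        )
        gsea_table = run_gsea(fit, boot, collection, gsea_term)
        gsea_table.to_csv(outdir / "gsea_results.csv", index=False)
        artifacts["gsea"] = str(outdir / "gsea_results.csv")

    if config.get("residuals"):
        resid = deviance_residuals(fit, assay)
        write_matrix(
            outdir / "residuals_combined.csv",
            resid.combined,
            resid.cell_ids,
            resid.gene_ids,
        )
        artifacts["residuals"] = str(outdir / "residuals_combined.csv")

    if config.get("scores"):
        nuisance = config.get("nuisance_terms", ["cdr"] if spec.include_cdr else [])
        scores = cell_scores(fit, assay, nuisance)
        scores.to_csv(outdir / "cell_scores.csv")
        artifacts["scores"] = str(outdir / "cell_scores.csv")
        if config.get("gmt"):
            mods = module_scores(scores, read_gmt(config["gmt"]))
            mods.to_csv(outdir / "module_scores.csv")
            artifacts["module_scores"] = str(outdir / "module_scores.csv")

    manifest = RunManifest(
        command="pipeline_run",
        config=config,
        input_checksums=checksums,
        seed=seed,
        version=__version__,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(outdir / "manifest.json")
    artifacts["manifest"] = str(outdir / "manifest.json")
    return artifacts
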