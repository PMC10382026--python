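"""File formats and run manifests.

Expression travels as TSV with genes as rows and a header of sample
ids; phenotype as CSV with a ``sample_id`` column plus ``response`` and
optional ``time_months``/``event``/``cluster``; gene sets as GMT; models
and manifests as JSON; panels as one-column gene-list text.  Readers
validate identifiers eagerly — duplicate gene ids and expression /
phenotype sample mismatches are rejected with the offending ids named —
and a transposed expression matrix (phenotype sample ids found among the
row names) is rejected with guidance rather than auto-fixed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .exceptions import InputError
from .genesets import GeneSetCollection, read_gmt, write_gmt  # noqa: F401  (re-exported surface)

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "read_gmt",
    "write_gmt",
    "check_cohort",
    "write_manifest",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column = gene ids)."""
    # round_trip parsing keeps write -> read -> write byte-identical
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise InputError(f"{path}: duplicate gene ids: {dups[:10]}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise InputError(f"{path}: duplicate sample ids: {dups[:10]}")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read a phenotype CSV indexed by sample_id."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise InputError(f"{path}: phenotype table needs a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise InputError(f"{path}: duplicate sample ids: {dups[:10]}")
    return df.set_index("sample_id")


def write_phenotype(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index_label="sample_id")


def check_cohort(expr: pd.DataFrame, pheno: pd.DataFrame) -> None:
    """Enforce sample-id agreement between expression and phenotype."""
    expr_samples = set(expr.columns)
    pheno_samples = set(pheno.index)
    if not (pheno_samples & expr_samples) and (pheno_samples & set(expr.index)):
        raise InputError(
            "expression matrix appears transposed (phenotype sample ids match its row names); "
            "provide genes as rows and samples as columns"
        )
    missing = sorted(expr_samples - pheno_samples)
    extra = sorted(pheno_samples - expr_samples)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"samples missing from phenotype: {missing[:10]}")
        if extra:
            parts.append(f"phenotype samples absent from expression: {extra[:10]}")
        raise InputError("; ".join(parts))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: str | Path, config: dict, seed: int, inputs: dict | None = None) -> Path:
    """Write a machine-readable run manifest enabling exact reruns.

    Records the configuration, seed, package version, and a sha256
    checksum of every input file.  Deliberately timestamp-free so a
    rerun from the same inputs is byte-identical.
    """
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(config, sort_keys=True)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "inputs": {
            # file name + checksum only: content-addressed and independent
            # of where the run happened, so reruns compare byte-identical
            name: {"file": Path(p).name, "sha256": _sha256(Path(p))}
            for name, p in (inputs or {}).items()
        },
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
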