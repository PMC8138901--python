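"""Readers and writers for the pipeline's on-disk formats.

All tables are plain text with explicit headers; writers prepend a comment
line ``# gexmorph.<kind>.v1`` identifying the format version, and readers
skip comment lines, so every output re-loads through these same functions
without loss. Expression matrices are TSV (probes x samples or genes x
regions), scan/sample metadata are CSV, gene-set catalogs are GMT, atlas
label volumes are NIfTI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._validate import ValidationError, require
from .enrichment import GeneSet, GeneSetCatalog
from .expression import AtlasSpec, DonorExpressionBundle
from .glm import LongitudinalDataset

_FLOAT_FMT = "%.10g"


def _write_table(df: pd.DataFrame, path, kind: str, sep: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# gexmorph.{kind}.v1\n")
        df.to_csv(fh, sep=sep, float_format=_FLOAT_FMT)


def _read_table(path, sep: str, index_col=0) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)
    except Exception as err:
        raise ValidationError(f"malformed table {path}: {err}") from None


def _require_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise ValidationError(
            f"{path}: non-numeric value {df.loc[r, c]!r} at row {r!r}, "
            f"column {c!r}")
    if numeric.isna().any().any():
        r = numeric.isna().any(axis=1).idxmax()
        raise ValidationError(f"{path}: missing value in row {r!r}")
    return numeric


# --- scan tables / responses ----------------------------------------------

def write_scan_table(dataset: LongitudinalDataset, path) -> None:
    _write_table(dataset.scans, path, "scans", ",")


def write_responses(dataset: LongitudinalDataset, path) -> None:
    _write_table(dataset.responses, path, "responses", "\t")


def read_dataset(scan_path, response_path) -> LongitudinalDataset:
    scans = _read_table(scan_path, ",")
    responses = _read_table(response_path, "\t")
    required = {"subject_id", "group", "age", "sex", "iq", "brain_size",
                "ses", "severity"}
    missing = required - set(scans.columns)
    require(not missing, f"{scan_path}: missing columns {sorted(missing)}")
    stutter = scans["group"] != "control"
    bad = scans.index[stutter & scans["severity"].isna()]
    if len(bad):
        raise ValidationError(
            f"{scan_path}: stuttering-group scans missing severity: "
            f"{list(bad)[:10]}")
    responses = _require_numeric(responses, response_path)
    return LongitudinalDataset(scans=scans, responses=responses,
                               regions=list(responses.columns)).validate()


# --- expression bundle -----------------------------------------------------

def write_bundle(bundle: DonorExpressionBundle, directory) -> dict[str, Path]:
    directory = Path(directory)
    paths = {
        "probes": directory / "probes.tsv",
        "samples": directory / "samples.csv",
        "expr": directory / "expression.tsv",
    }
    _write_table(bundle.probes, paths["probes"], "probes", "\t")
    _write_table(bundle.samples, paths["samples"], "samples", ",")
    _write_table(bundle.expr, paths["expr"], "expression", "\t")
    return paths


def read_bundle(probe_path, sample_path, expr_path) -> DonorExpressionBundle:
    probes = _read_table(probe_path, "\t")
    samples = _read_table(sample_path, ",")
    expr = _require_numeric(_read_table(expr_path, "\t"), expr_path)
    require("gene_symbol" in probes.columns,
            f"{probe_path}: missing 'gene_symbol' column")
    for col in ("donor_id", "x", "y", "z"):
        require(col in samples.columns, f"{sample_path}: missing {col!r}")
    expr.columns.name = samples.index.name
    return DonorExpressionBundle(probes=probes, samples=samples,
                                 expr=expr).validate()


def write_whitelist(symbols, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(sorted(symbols)) + "\n")


def read_whitelist(path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    symbols = [ln for ln in lines if ln and not ln.startswith("#")]
    require(len(symbols) > 0, f"{path}: empty whitelist")
    return symbols


# --- atlas -----------------------------------------------------------------

def write_atlas(atlas: AtlasSpec, directory) -> dict[str, Path]:
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"regions": directory / "regions.csv",
             "labels": directory / "labels.nii",
             "label_map": directory / "label_map.json"}
    _write_table(atlas.regions, paths["regions"], "regions", ",")
    if atlas.label_img is not None:
        nib.save(atlas.label_img, paths["labels"])
        paths["label_map"].write_text(json.dumps(
            {str(k): v for k, v in atlas.label_map.items()}, indent=1))
    return paths


def read_atlas(region_path, label_path=None, label_map_path=None) -> AtlasSpec:
    regions = _read_table(region_path, ",")
    for col in ("supratentorial", "cerebellum"):
        if col in regions.columns:
            regions[col] = regions[col].astype(bool)
    img, label_map = None, {}
    if label_path is not None:
        import nibabel as nib
        img = nib.load(label_path)
        require(label_map_path is not None,
                "a label volume requires a label_map JSON")
        label_map = {int(k): v for k, v in
                     json.loads(Path(label_map_path).read_text()).items()}
    return AtlasSpec(regions=regions, label_img=img,
                     label_map=label_map).validate()


# --- GMT catalogs ----------------------------------------------------------

def write_gmt(catalog: GeneSetCatalog, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in catalog.sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.id}\t{gs.name}\t{members}\n")


def read_gmt(path) -> GeneSetCatalog:
    sets = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path}:{i}: GMT record needs id, description and >= 1 member")
        sets.append(GeneSet(id=parts[0], name=parts[1],
                            members=frozenset(parts[2:])))
    return GeneSetCatalog(sets=sets, source=str(path)).validate()


# --- result tables ---------------------------------------------------------

def write_association(assoc: pd.DataFrame, path) -> None:
    _write_table(assoc, path, "association", "\t")


def read_association(path) -> pd.DataFrame:
    return _read_table(path, "\t")


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
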