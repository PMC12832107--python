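"""Readers and writers for panels, annotations and result files.

Count and TPM matrices are delimited text with genes as rows (first column
gene identifier) and clones as columns (header row); tab or comma
delimiters are auto-detected.  Annotation lists are plain text, one gene
symbol per line.  Every output directory carries a JSON run manifest with
the tool version, the full configuration and its hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .panel import ANNOTATION_CATEGORIES, ClonePanel

__all__ = [
    "read_matrix",
    "read_annotations",
    "read_panel",
    "write_panel",
    "write_json",
    "write_manifest",
    "config_hash",
]

logger = logging.getLogger("rmescope")

_ANNOTATION_FILES = {
    "X_LINKED": "x_linked.txt",
    "Y_LINKED": "y_linked.txt",
    "IMPRINTED": "imprinted.txt",
}


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(path: str | Path, name: str = "matrix") -> pd.DataFrame:
    """Read one genes x clones matrix, validating labels and values.

    Missing cells become 0 (with a logged warning count); duplicate gene or
    clone identifiers and non-numeric cells are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{name} ({path.name}): duplicate gene identifiers {dups}")
    if pd.Index(df.columns).has_duplicates:
        raise ValueError(f"{name} ({path.name}): duplicate clone identifiers")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{name} ({path.name}): non-numeric cell: {exc}") from exc
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("%s (%s): %d missing cells treated as zero", name, path.name, n_missing)
        df = df.fillna(0)
    return df


def read_annotations(paths: dict[str, str | Path]) -> dict[str, frozenset[str]]:
    """Read annotation gene lists; keys of ``paths`` are annotation categories."""
    ann: dict[str, set[str]] = {}
    for category, path in paths.items():
        if category not in ANNOTATION_CATEGORIES:
            raise ValueError(f"unknown annotation category {category!r}")
        for line in Path(path).read_text().splitlines():
            gene = line.strip()
            if gene and not gene.startswith("#"):
                ann.setdefault(gene, set()).add(category)
    return {g: frozenset(c) for g, c in ann.items()}


def annotations_from_dir(directory: str | Path) -> dict[str, frozenset[str]]:
    """Load x_linked.txt / y_linked.txt / imprinted.txt found in a directory."""
    directory = Path(directory)
    paths = {
        cat: directory / fname
        for cat, fname in _ANNOTATION_FILES.items()
        if (directory / fname).exists()
    }
    return read_annotations(paths)


def _check_labels(reference: pd.DataFrame, other: pd.DataFrame, name: str) -> pd.DataFrame:
    missing_genes = sorted(set(reference.index) - set(other.index))
    extra_genes = sorted(set(other.index) - set(reference.index))
    if missing_genes or extra_genes:
        raise ValueError(
            f"{name}: gene identifiers do not match the CAST matrix "
            f"(missing: {missing_genes[:5]}, unexpected: {extra_genes[:5]})"
        )
    missing_clones = sorted(set(reference.columns) - set(other.columns))
    extra_clones = sorted(set(other.columns) - set(reference.columns))
    if missing_clones or extra_clones:
        raise ValueError(
            f"{name}: clone identifiers do not match the CAST matrix "
            f"(missing: {missing_clones[:5]}, unexpected: {extra_clones[:5]})"
        )
    return other.loc[reference.index, reference.columns]


def read_panel(
    cast_path: str | Path,
    r129_path: str | Path,
    tpm_path: str | Path,
    annotations: dict[str, frozenset[str]] | None = None,
    annotations_dir: str | Path | None = None,
    clone_meta_path: str | Path | None = None,
    cast_tpm_path: str | Path | None = None,
    r129_tpm_path: str | Path | None = None,
) -> ClonePanel:
    """Assemble a validated ClonePanel from matrix files.

    The three matrices must agree on gene and clone identifiers (order is
    reconciled to the CAST matrix); mismatches raise with the offending
    identifiers named.
    """
    cast = read_matrix(cast_path, "CAST counts")
    r129 = _check_labels(cast, read_matrix(r129_path, "129 counts"), "129 counts")
    tpm = _check_labels(cast, read_matrix(tpm_path, "TPM"), "TPM")
    ann = dict(annotations or {})
    if annotations_dir is not None:
        ann.update(annotations_from_dir(annotations_dir))
    clone_meta = None
    if clone_meta_path is not None:
        p = Path(clone_meta_path)
        clone_meta = pd.read_csv(p, sep=_detect_sep(p), index_col=0)
    cast_tpm = r129_tpm = None
    if cast_tpm_path is not None:
        cast_tpm = _check_labels(cast, read_matrix(cast_tpm_path, "CAST TPM"), "CAST TPM")
    if r129_tpm_path is not None:
        r129_tpm = _check_labels(cast, read_matrix(r129_tpm_path, "129 TPM"), "129 TPM")
    return ClonePanel(
        cast=cast, r129=r129, tpm=tpm, clone_meta=clone_meta,
        annotations=ann, cast_tpm=cast_tpm, r129_tpm=r129_tpm,
    )


def write_panel(panel: ClonePanel, out_dir: str | Path, sep: str = "\t") -> dict[str, Path]:
    """Write the panel matrices (and annotations/metadata) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if sep == "\t" else "csv"
    paths = {
        "cast": out / f"cast_counts.{ext}",
        "r129": out / f"129_counts.{ext}",
        "tpm": out / f"tpm.{ext}",
    }
    panel.cast.to_csv(paths["cast"], sep=sep)
    panel.r129.to_csv(paths["r129"], sep=sep)
    panel.tpm.to_csv(paths["tpm"], sep=sep)
    if panel.cast_tpm is not None:
        paths["cast_tpm"] = out / f"cast_tpm.{ext}"
        panel.cast_tpm.to_csv(paths["cast_tpm"], sep=sep)
    if panel.r129_tpm is not None:
        paths["r129_tpm"] = out / f"129_tpm.{ext}"
        panel.r129_tpm.to_csv(paths["r129_tpm"], sep=sep)
    if panel.clone_meta is not None:
        paths["clone_meta"] = out / f"clone_meta.{ext}"
        panel.clone_meta.to_csv(paths["clone_meta"], sep=sep)
    for category, fname in _ANNOTATION_FILES.items():
        genes = sorted(g for g, cats in panel.annotations.items() if category in cats)
        if genes:
            p = out / fname
            p.write_text("\n".join(genes) + "\n")
            paths[category] = p
    return paths


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_manifest(out_dir: str | Path, command: str, config: dict) -> Path:
    """Write the machine-readable run manifest next to a command's outputs."""
    from . import __version__

    manifest = {
        "tool": "rmescope",
        "version": __version__,
        "command": command,
        "config": config,
        "config_hash": config_hash(config),
    }
    path = Path(out_dir) / "manifest.json"
    write_json(manifest, path)
    return path
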