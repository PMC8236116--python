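"""Readers and writers for the plain-text formats used throughout.

All tables are tab-separated with a header row.  Blocks are written features
as rows with the feature id in the first column; metadata tables carry
``sample_id``, ``group`` and ``patient_id`` columns; gene sets use the
standard GMT dialect (set name, description, then member symbols).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .blocks import MultiOmicsDataset, OmicsBlock

__all__ = [
    "read_block_tsv",
    "write_block_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_traits_tsv",
    "write_traits_tsv",
    "read_symbol_map",
    "write_symbol_map",
    "read_gmt",
    "write_gmt",
    "load_dataset",
    "save_dataset",
]


def read_block_tsv(path: str | Path, name: str | None = None) -> OmicsBlock:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsBlock(name or Path(path).stem, df)


def write_block_tsv(block: OmicsBlock, path: str | Path) -> None:
    df = block.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}, got {list(meta.columns)}")
    return meta.set_index("sample_id")


def write_metadata_tsv(
    y: pd.Series, patient_id: pd.Series | None, path: str | Path
) -> None:
    meta = pd.DataFrame({"sample_id": y.index, "group": y.to_numpy()})
    if patient_id is not None:
        meta["patient_id"] = patient_id.to_numpy()
    meta.to_csv(path, sep="\t", index=False)


def read_traits_tsv(path: str | Path) -> pd.DataFrame:
    traits = pd.read_csv(path, sep="\t", index_col=0)
    traits.index = traits.index.astype(str)
    return traits


def write_traits_tsv(traits: pd.DataFrame, path: str | Path) -> None:
    out = traits.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_symbol_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (feature id, gene symbol) -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("symbol map needs two columns: feature_id, symbol")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_symbol_map(symbol_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"feature_id": list(symbol_map), "symbol": list(symbol_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into {set name: member symbols}."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def load_dataset(
    block_paths: dict[str, str | Path],
    metadata_path: str | Path,
    traits_path: str | Path | None = None,
    positive_label: str | None = None,
) -> MultiOmicsDataset:
    """Assemble a :class:`MultiOmicsDataset` from TSV files on disk."""
    blocks = [read_block_tsv(p, name) for name, p in block_paths.items()]
    meta = read_metadata_tsv(metadata_path)
    sample_ids = blocks[0].sample_ids
    y = meta["group"].reindex(sample_ids)
    pid = meta["patient_id"].reindex(sample_ids) if "patient_id" in meta.columns else None
    traits = read_traits_tsv(traits_path) if traits_path else None
    return MultiOmicsDataset(blocks, y, pid, traits, positive_label=positive_label)


def save_dataset(data: MultiOmicsDataset, outdir: str | Path) -> dict[str, str]:
    """Write every component of a dataset to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for b in data.blocks:
        p = outdir / f"block_{b.name}.tsv"
        write_block_tsv(b, p)
        paths[f"block_{b.name}"] = str(p)
    p = outdir / "metadata.tsv"
    write_metadata_tsv(data.y, data.patient_id, p)
    paths["metadata"] = str(p)
    if data.traits is not None:
        p = outdir / "traits.tsv"
        write_traits_tsv(data.traits, p)
        paths["traits"] = str(p)
    return paths


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
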