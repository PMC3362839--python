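"""File formats: TSV peak tables and matrices, NEXUS binary characters,
Newick trees, JSON reports and manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .data import BinaryCharacterMatrix, PeakHeightTable
from .errors import ParseError
from .nj import SupportTable
from .trees import Bipartition

__all__ = [
    "write_peak_table", "read_peak_table",
    "write_binary_matrix", "read_binary_matrix",
    "write_support_table", "write_tree", "read_tree",
    "write_json", "file_sha256",
]


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

def write_peak_table(peaks: PeakHeightTable, path: str | Path) -> None:
    """TSV with bin sizes as columns; sidecar ``<stem>.pairs.tsv`` and
    ``<stem>.species.tsv`` hold replicate pairing and the species map."""
    path = Path(path)
    df = pd.DataFrame(peaks.heights, index=peaks.sample_ids,
                      columns=[f"{b:g}" for b in peaks.bin_sizes])
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
    pairs = pd.DataFrame(peaks.replicate_pairs, columns=["sample", "replicate"])
    pairs.to_csv(path.with_suffix(".pairs.tsv"), sep="\t", index=False)
    _write_species_map(peaks.species_map, path.with_suffix(".species.tsv"))


def read_peak_table(path: str | Path) -> PeakHeightTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    pairs_path = path.with_suffix(".pairs.tsv")
    pairs: list[tuple[str, str]] = []
    if pairs_path.exists():
        pdf = pd.read_csv(pairs_path, sep="\t", dtype=str)
        pairs = [tuple(r) for r in pdf.to_numpy()]
    species = _read_species_map(path.with_suffix(".species.tsv"))
    try:
        bins = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ParseError(f"non-numeric bin label in {path}: {exc}") from None
    return PeakHeightTable(df.to_numpy(dtype=float), [str(i) for i in df.index],
                           bins, pairs, species)


def _write_species_map(species_map: dict[str, str], path: Path) -> None:
    df = pd.DataFrame(sorted(species_map.items()), columns=["sample", "species"])
    df.to_csv(path, sep="\t", index=False)


def _read_species_map(path: Path) -> dict[str, str]:
    if not Path(path).exists():
        return {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["species"]))


# ---------------------------------------------------------------------------
# binary matrices (TSV and NEXUS standard datatype)
# ---------------------------------------------------------------------------

def write_binary_matrix(matrix: BinaryCharacterMatrix, path: str | Path,
                        dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        df = pd.DataFrame(matrix.calls, index=matrix.sample_ids, columns=matrix.locus_ids)
        df.index.name = "sample"
        df.to_csv(path, sep="\t")
    elif dialect == "nexus-binary":
        char_dict = {s: "".join(str(v) for v in row)
                     for s, row in zip(matrix.sample_ids, matrix.calls)}
        cm = dendropy.StandardCharacterMatrix.from_dict(char_dict)
        cm.write(path=str(path), schema="nexus")
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    _write_species_map(matrix.species_map, path.with_suffix(".species.tsv"))


def read_binary_matrix(path: str | Path, dialect: str = "tsv") -> BinaryCharacterMatrix:
    """Read and validate a 0/1 matrix; species map from the sidecar TSV."""
    path = Path(path)
    species = _read_species_map(path.with_suffix(".species.tsv"))
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        arr = df.to_numpy()
        bad = np.argwhere(~np.isin(arr, (0, 1)))
        if bad.size:
            i, j = bad[0]
            raise ParseError(
                f"non-binary cell at sample {df.index[i]!r}, locus {df.columns[j]!r}: "
                f"{arr[i, j]!r}"
            )
        sample_ids = [str(i) for i in df.index]
        if len(set(sample_ids)) != len(sample_ids):
            raise ParseError("duplicate sample id in matrix")
        return BinaryCharacterMatrix(arr.astype(np.int8), sample_ids,
                                     [str(c) for c in df.columns], species)
    if dialect == "nexus-binary":
        cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        sample_ids, rows = [], []
        for taxon in cm:
            seq = cm[taxon].symbols_as_string()
            if set(seq) - {"0", "1"}:
                bad_sym = sorted(set(seq) - {"0", "1"})[0]
                raise ParseError(f"non-binary symbol {bad_sym!r} for taxon {taxon.label!r}")
            sample_ids.append(taxon.label)
            rows.append([int(c) for c in seq])
        arr = np.asarray(rows, dtype=np.int8)
        locus_ids = [f"L{j + 1:04d}" for j in range(arr.shape[1])]
        return BinaryCharacterMatrix(arr, sample_ids, locus_ids, species)
    raise ParseError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# trees and support
# ---------------------------------------------------------------------------

def write_tree(tree: dendropy.Tree, path: str | Path,
               support: dict[Bipartition, float] | None = None,
               min_displayed_support: float | None = None) -> None:
    from .trees import to_newick

    Path(path).write_text(to_newick(tree, support, min_displayed_support) + "\n")


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_support_table(table: SupportTable, path: str | Path) -> None:
    rows = [
        {"bipartition": "|".join(sorted(bp.side)), "support": val}
        for bp, val in sorted(table.entries.items(), key=lambda kv: sorted(kv[0].side))
    ]
    df = pd.DataFrame(rows, columns=["bipartition", "support"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JSON + manifests
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable) + "\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
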