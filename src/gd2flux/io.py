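"""Tabular readers/writers and provenance headers.

All TSV outputs start with comment lines recording the tool version, a
configuration hash, and the seed, so every artifact is traceable to the
run that produced it; all readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .errors import InputError
from .graph import ReactionSet


def config_hash(config: Mapping) -> str:
    blob = json.dumps({k: str(v) for k, v in sorted(config.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def provenance_header(config: Optional[Mapping] = None,
                      seed: Optional[int] = None, **extra) -> str:
    fields = {"tool": f"gd2flux {__version__}"}
    if config is not None:
        fields["config"] = config_hash(config)
    if seed is not None:
        fields["seed"] = seed
    fields.update(extra)
    return "# " + " ".join(f"{k}={v}" for k, v in fields.items())


def write_tsv(df: pd.DataFrame, path: str | Path, header: Optional[str] = None,
              index_label: str = "id") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples count matrix TSV (first column gene symbols)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        raise InputError(f"{path}: duplicated gene identifiers")
    if df.columns.duplicated().any():
        raise InputError(f"{path}: duplicated sample identifiers")
    return df


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Generic samples-as-rows matrix TSV (RAS, features, scores)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_metadata(path: str | Path, label_column: str = "label") -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if label_column not in meta.columns and meta.shape[1] >= 1:
        meta = meta.rename(columns={meta.columns[0]: label_column})
    return meta


def read_gpr_table(path: str | Path) -> dict[str, str]:
    """GPR TSV with columns reaction_id, gpr_rule."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected columns reaction_id, gpr_rule")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_gpr_table(rules: Mapping[str, str], path: str | Path,
                    header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        fh.write("reaction_id\tgpr_rule\n")
        for rid in sorted(rules):
            fh.write(f"{rid}\t{rules[rid]}\n")


def read_reaction_sets(path: str | Path) -> list[ReactionSet]:
    doc = json.loads(Path(path).read_text())
    if isinstance(doc, Mapping):
        doc = [doc]
    return [ReactionSet.from_dict(d) for d in doc]


def write_reaction_sets(sets, path: str | Path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in sets], indent=1))
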