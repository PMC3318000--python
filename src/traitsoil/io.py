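"""Plain-text interchange: TSV with comment-prefixed provenance headers, Newick trees."""
from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd

from . import __version__


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: list[str] | None = None,
              index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# traitsoil {__version__}\n")
        for line in provenance or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def normalize_species(label: str) -> str:
    """Case-fold and unify space/underscore so tree and table codes match."""
    return label.strip().casefold().replace(" ", "_")
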