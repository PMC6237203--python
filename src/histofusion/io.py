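"""Readers and writers for the on-disk formats the pipeline exchanges.

Expression matrices are genes x samples TSV (gene symbols in the first
column, sample IDs in the header).  Gene-signature panels use the GMT
convention: one set per line, ``name<TAB>description<TAB>gene1<TAB>gene2...``.
Clinical tables are plain TSV keyed by ``patient_id``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix (gene symbols as index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene symbols in expression matrix")
    return df.astype(float)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT signature panel into ``{name: [genes...]}``.

    The description field (second column) is discarded.  Duplicate set
    names or empty gene lists are rejected.
    """
    panel: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"signature {name!r} has no genes")
        if name in panel:
            raise ValueError(f"duplicate signature name {name!r}")
        panel[name] = genes
    return panel


def write_gmt(panel: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in panel.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return df.set_index("patient_id")


def write_clinical_tsv(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index_label="patient_id")


def read_slide(path: str | Path) -> np.ndarray:
    """Load a slide raster (PNG or TIFF) as a uint8 array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path))
    return np.asarray(Image.open(path))


def write_slide(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, image)
    else:
        Image.fromarray(image).save(path)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
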