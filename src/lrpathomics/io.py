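"""Plain-text readers and writers for the pipeline's artifacts.

Expression matrices travel as TSV (genes in rows) or MatrixMarket;
survival tables and pair statistics as CSV; catalogs as TSV; slides as
PNG; planted truth and fitted stain models as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import io as spio
from scipy.sparse import csr_matrix


def write_expression_tsv(expr: pd.DataFrame, path):
    expr.to_csv(path, sep="\t")


def read_expression_tsv(path, normalized: bool = False) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.attrs["normalized"] = normalized
    return expr


def write_expression_mtx(expr: pd.DataFrame, prefix):
    """MatrixMarket triple: {prefix}.mtx plus gene/sample id lists."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(expr.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(expr.index) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(expr.columns) + "\n")


def read_expression_mtx(prefix, normalized: bool = False) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    expr = pd.DataFrame(mat, index=genes, columns=samples)
    expr.attrs["normalized"] = normalized
    return expr


def write_survival_csv(surv: pd.DataFrame, path):
    surv.to_csv(path)


def read_survival_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_catalog_tsv(catalog: pd.DataFrame, path):
    catalog.to_csv(path, sep="\t")


def read_catalog_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_png(image: np.ndarray, path):
    Image.fromarray(image).save(path)


def read_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_json(obj, path):
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
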