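"""Readers and writers for phenotype tables and fitted models.

Tables are plain delimited text, one row per variant: a genotype column
holding the per-site state tokens (joined by the space's token delimiter)
and one or more phenotype replicate columns.  Models are a structured
JSON document (format ``rfa-model/1``) holding the space description,
intercept, link parameters, and a flat term table; writing and reading a
model round-trips bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_space import GenotypeSpace, TermKey
from .nonspecific_link import LinkParams
from .rfa_exact import EffectSet, PhenotypeTable

__all__ = ["TableFileSpec", "read_table", "write_table", "read_model", "write_model"]

logger = logging.getLogger(__name__)

MODEL_FORMAT = "rfa-model/1"


@dataclass(frozen=True)
class TableFileSpec:
    """How to parse a phenotype table file."""

    path: str | Path
    delimiter: str = "\t"
    genotype_column: str = "genotype"
    phenotype_columns: tuple[str, ...] | None = None  # None: all other columns
    token_delimiter: str | None = None  # None: infer (single-char tokens)
    missing: str = "NA"
    space: GenotypeSpace | None = None


def _infer_space(strings: list[str], token_delimiter: str | None) -> GenotypeSpace:
    if token_delimiter:
        tokenized = [s.split(token_delimiter) for s in strings]
    else:
        tokenized = [list(s) for s in strings]
    lengths = {len(t) for t in tokenized}
    if len(lengths) != 1:
        raise ValueError(f"ragged genotype strings: lengths {sorted(lengths)}")
    n = lengths.pop()
    alphabets = []
    for i in range(n):
        toks = sorted({t[i] for t in tokenized})
        if len(toks) < 2:
            raise ValueError(
                f"site {i + 1} shows only one state ({toks[0]!r}); "
                "declare the space explicitly"
            )
        alphabets.append(tuple(toks))
    return GenotypeSpace(tuple(alphabets), token_delimiter=token_delimiter or "")


def read_table(spec: TableFileSpec | str | Path) -> PhenotypeTable:
    """Read a delimited genotype-phenotype file.

    Per-site alphabets are inferred as the sorted set of observed tokens
    unless a space is declared.  Duplicate genotypes are merged as extra
    replicates; rows with no finite phenotype are dropped with a logged
    count.
    """
    if not isinstance(spec, TableFileSpec):
        spec = TableFileSpec(path=spec)
    df = pd.read_csv(
        spec.path, sep=spec.delimiter, na_values=[spec.missing], dtype={0: str}
    )
    if spec.genotype_column not in df.columns:
        raise ValueError(
            f"no {spec.genotype_column!r} column in {spec.path} "
            f"(found {list(df.columns)})"
        )
    pheno_cols = (
        list(spec.phenotype_columns)
        if spec.phenotype_columns
        else [c for c in df.columns if c != spec.genotype_column]
    )
    if not pheno_cols:
        raise ValueError("no phenotype columns found")
    values = df[pheno_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    keep = ~np.all(np.isnan(values), axis=1)
    if (n_drop := int((~keep).sum())):
        logger.info("dropped %d row(s) with no phenotype value", n_drop)
    df, values = df.loc[keep], values[keep]
    if len(df) == 0:
        raise ValueError(f"no usable rows in {spec.path}")
    strings = df[spec.genotype_column].astype(str).tolist()
    space = spec.space
    if space is None:
        space = _infer_space(strings, spec.token_delimiter)
    genotypes = np.stack([space.parse_genotype(s) for s in strings])
    return PhenotypeTable.from_rows(space, genotypes, values)


def write_table(table: PhenotypeTable, path: str | Path, delimiter: str = "\t") -> None:
    cols = {
        "genotype": [table.space.format_genotype(g) for g in table.genotypes]
    }
    for j in range(table.n_replicates):
        cols[f"phenotype_{j + 1}"] = table.phenotypes[:, j]
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------


def write_model(effects: EffectSet, path: str | Path, metadata: dict | None = None) -> None:
    """Serialize an effect set (with link and space) as structured JSON."""
    space = effects.space
    terms = [
        {
            "order": key.order,
            "sites": [i + 1 for i in key.sites],
            "states": [
                space.site_alphabets[i][s] for i, s in zip(key.sites, key.states)
            ],
            "value": value,
        }
        for key, value in effects.term_items()
    ]
    doc = {
        "format": MODEL_FORMAT,
        "space": space.describe(),
        "max_order": effects.max_order,
        "intercept": effects.intercept,
        "link": None
        if effects.link is None
        else {"type": "sigmoid", "L": effects.link.L, "U": effects.link.U},
        "terms": terms,
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path: str | Path) -> EffectSet:
    doc = json.loads(Path(path).read_text())
    fmt = doc.get("format")
    if fmt != MODEL_FORMAT:
        raise ValueError(
            f"unsupported model format {fmt!r} (this build reads {MODEL_FORMAT})"
        )
    space = GenotypeSpace.from_description(doc["space"])
    link = None
    if doc.get("link") is not None:
        link = LinkParams(doc["link"]["L"], doc["link"]["U"])
    terms: dict[TermKey, float] = {}
    for t in doc["terms"]:
        sites = tuple(i - 1 for i in t["sites"])
        states = tuple(
            space.site_alphabets[i].index(s) for i, s in zip(sites, t["states"])
        )
        terms[TermKey(sites, states)] = float(t["value"])
    return EffectSet.from_terms(
        space, float(doc["intercept"]), terms,
        max_order=doc.get("max_order"), link=link,
    )
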