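"""Plain-text readers/writers for every table the pipeline exchanges.

Everything on disk is TSV (BED-like where genomic, 0-based half-open)
or GMT (one named gene set per line). Writers and readers round-trip
losslessly for the columns they own.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import ExpressionMatrix


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_depth_track(track: pd.DataFrame, path: str | Path) -> None:
    write_table(track[["chrom", "start", "end", "count"]], path)


def read_depth_track(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    return df.astype({"start": int, "end": int})


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Genes x libraries counts with a role row and a totals row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = matrix.counts.copy()
    roles = matrix.roles[header.columns]
    totals = matrix.totals[header.columns]
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(header.columns) + "\n")
        fh.write("#role\t" + "\t".join(roles.astype(str)) + "\n")
        fh.write("#total\t" + "\t".join(str(int(t)) for t in totals) + "\n")
        header.to_csv(fh, sep="\t", header=False)


def read_expression(path: str | Path) -> ExpressionMatrix:
    with open(path) as fh:
        libs = fh.readline().rstrip("\n").split("\t")[1:]
        roles = fh.readline().rstrip("\n").split("\t")[1:]
        totals = [int(x) for x in fh.readline().rstrip("\n").split("\t")[1:]]
        counts = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    counts.columns = libs
    counts.index.name = "gene_id"
    return ExpressionMatrix(
        counts=counts,
        roles=pd.Series(roles, index=libs),
        totals=pd.Series(totals, index=libs),
    )


def write_gmt(gene_sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in gene_sets:
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(gene_sets[name])]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(parts[2:])
    return out
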