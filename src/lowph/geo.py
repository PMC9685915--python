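"""GEO series-matrix ingestion for reproducing the analysis from the deposited data.

The deposited accession for this study design is GSE210964.  A series-matrix
file is plain text: ``!``-prefixed metadata lines and a tab-separated
expression table between ``!series_matrix_table_begin`` and
``!series_matrix_table_end``.  Because GEO sample titles cannot be assumed,
the mapping from GSM accession to (strain, condition, replicate) is supplied
by the caller as an editable TSV rather than guessed.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

import pandas as pd

from .expression import DesignError, ExpressionMatrix

GEO_SERIES_MATRIX_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/{prefix}nnn/{accession}/matrix/"
    "{accession}_series_matrix.txt.gz"
)


def parse_series_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Parse a (decompressed) series-matrix file.

    Returns the expression table (probes/genes x GSM columns) and a dict of
    GSM accession -> sample title taken from the metadata header.
    """
    titles: dict[str, str] = {}
    header_lines: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line[1:].partition("\t")
                header_lines.setdefault(key, []).append(rest)
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix table found")

    def _unquote(s: str) -> str:
        return s.strip('"')

    header = [_unquote(c) for c in table_lines[0].split("\t")]
    rows = [
        [_unquote(c) for c in line.split("\t")] for line in table_lines[1:] if line
    ]
    table = pd.DataFrame(rows, columns=header).set_index(header[0])
    table = table.apply(pd.to_numeric, errors="coerce")
    table.index.name = "gene"

    accessions = [
        _unquote(a) for a in header_lines.get("Sample_geo_accession", [""])[0].split("\t")
    ]
    title_row = header_lines.get("Sample_title", [""])[0].split("\t")
    for acc, title in zip(accessions, (_unquote(t) for t in title_row)):
        if acc:
            titles[acc] = title
    return table, titles


def read_sample_mapping(path: str | Path) -> pd.DataFrame:
    """Read the user-edited GSM -> design mapping TSV.

    Columns: ``sample_id`` (GSM accession), ``strain``, ``condition``,
    ``replicate``.
    """
    mapping = pd.read_csv(path, sep="\t", dtype={"replicate": "Int64"})
    required = {"sample_id", "strain", "condition", "replicate"}
    missing = required - set(mapping.columns)
    if missing:
        raise DesignError(f"mapping file missing columns: {sorted(missing)}")
    if mapping[["strain", "condition", "replicate"]].isna().any().any():
        unmapped = mapping.loc[
            mapping[["strain", "condition", "replicate"]].isna().any(axis=1), "sample_id"
        ]
        raise DesignError(f"unmapped samples in mapping file: {list(unmapped)}")
    return mapping.set_index("sample_id")


def write_mapping_template(titles: dict[str, str], path: str | Path) -> None:
    """Emit an editable mapping template with blank design columns."""
    pd.DataFrame(
        {
            "sample_id": list(titles),
            "title": [titles[a] for a in titles],
            "strain": "",
            "condition": "",
            "replicate": "",
        }
    ).to_csv(path, sep="\t", index=False)


def fetch_accession(
    accession: str,
    cache_dir: str | Path,
    mapping_file: str | Path,
    download: bool = True,
) -> ExpressionMatrix:
    """Load a GEO series matrix (cache-first) as a validated ExpressionMatrix.

    If ``<cache_dir>/<accession>_series_matrix.txt`` exists it is used
    without touching the network; otherwise the series matrix is downloaded
    from the GEO FTP mirror (requires network) and cached decompressed.
    Never fabricates data: any download or parse failure raises.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    cached = cache_dir / f"{accession}_series_matrix.txt"
    if not cached.exists():
        if not download:
            raise FileNotFoundError(f"no cached series matrix at {cached} and download=False")
        import gzip

        url = GEO_SERIES_MATRIX_URL.format(prefix=accession[:-3], accession=accession)
        gz_path = cached.with_suffix(".txt.gz")
        urllib.request.urlretrieve(url, gz_path)
        cached.write_text(gzip.open(gz_path, "rt").read())
    table, _titles = parse_series_matrix(cached)
    mapping = read_sample_mapping(mapping_file)
    missing = set(table.columns) - set(mapping.index)
    if missing:
        raise DesignError(f"samples without design mapping: {sorted(missing)}")
    samples = mapping.loc[list(table.columns), ["strain", "condition", "replicate"]].astype(
        {"replicate": int}
    )
    return ExpressionMatrix(values=table, samples=samples)
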