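"""Readers and writers for the on-disk formats the pipeline consumes.

* peak-list CSV per sample/solvent: columns mz, intensity, C, H, O, N,
  S, P (empty element fields mean the peak was not formula-assigned);
* OTU table TSV, samples x OTUs or transposed (orientation detected
  from the first header cell);
* taxonomy TSV: otu_id, rank labels, per-rank confidence columns;
* DOC CSV: sample, doc (mg C/L);
* ground-truth and manifest JSON;
* boundary table YAML/CSV.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd
import yaml

from .chem import BoundaryTable, FticrSample

__all__ = [
    "read_peak_csv",
    "write_peak_csv",
    "read_fticr_dir",
    "write_fticr_dir",
    "read_otu_tsv",
    "write_otu_tsv",
    "read_taxonomy_tsv",
    "write_taxonomy_tsv",
    "read_doc_csv",
    "write_doc_csv",
    "read_boundaries",
    "write_boundaries",
    "read_ground_truth",
    "write_ground_truth",
]


def read_peak_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_peak_csv(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, index=False)


_PEAK_FILE = re.compile(r"(?P<sample>.+)__(?P<solvent>[a-z]+)\.csv$")


def write_fticr_dir(samples: list[FticrSample], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        for solvent, peaks in s.peak_lists.items():
            write_peak_csv(peaks, outdir / f"{s.sample_id}__{solvent}.csv")


def read_fticr_dir(indir) -> list[FticrSample]:
    by_sample: dict[str, FticrSample] = {}
    for path in sorted(Path(indir).glob("*.csv")):
        m = _PEAK_FILE.match(path.name)
        if not m:
            continue
        sid, solvent = m.group("sample"), m.group("solvent")
        by_sample.setdefault(sid, FticrSample(sample_id=sid))
        by_sample[sid].peak_lists[solvent] = read_peak_csv(path)
    return list(by_sample.values())


def write_otu_tsv(counts: pd.DataFrame, path) -> None:
    """Samples as rows; first column header is 'sample'."""
    out = counts.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_otu_tsv(path) -> pd.DataFrame:
    """Auto-orient: header cell 'sample' means samples x OTUs, 'otu'/'otu_id' the transpose."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    first = (df.index.name or "").strip().lower()
    if first in ("otu", "otu_id", "otuid"):
        df = df.T
    df.index.name = "sample"
    return df.astype(int)


def write_taxonomy_tsv(tax: pd.DataFrame, path) -> None:
    out = tax.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def read_taxonomy_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_doc_csv(doc: pd.Series, path) -> None:
    doc.rename("doc").rename_axis("sample").to_csv(path)


def read_doc_csv(path) -> pd.Series:
    df = pd.read_csv(path, index_col=0)
    return df.iloc[:, 0].rename("doc")


def write_boundaries(table: BoundaryTable, path) -> None:
    path = Path(path)
    records = table.to_records()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(records, sort_keys=False))
    else:
        pd.DataFrame(records).to_csv(path, index=False)


def read_boundaries(path) -> BoundaryTable:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        records = yaml.safe_load(path.read_text())
    else:
        records = pd.read_csv(path).to_dict(orient="records")
    return BoundaryTable.from_records(records)


def write_ground_truth(truth, path) -> None:
    payload = {
        "planted_taxa": truth.planted_taxa,
        "class_doc_signs": truth.class_doc_signs,
        "cohort_labels": truth.cohort_labels,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
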