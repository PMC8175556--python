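"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (first column feature id, header row of
sample ids); clinical tables as CSV; gene sets as GMT; signatures and drug
models as JSON.  Readers validate shape and identifiers and report the
offending line on failure; writers emit stable column order and a trailing
newline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from pcatx.drug_response import DrugResponseModel
from pcatx.pathway import GeneSet, SignatureModel

CLINICAL_COLUMNS = ["sample_id", "group", "grade_group", "pt_stage", "pn_stage", "psa"]


def read_expression(path) -> pd.DataFrame:
    """Read a features x samples TSV expression matrix.

    Rejects ragged rows, duplicate feature ids, and non-numeric cells, naming
    the offending line.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must contain at least one sample column")
        samples = header[1:]
        n_cols = len(header)
        features, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(parts)}"
                )
            features.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if len(set(features)) != len(features):
        seen: set[str] = set()
        dupes = sorted({f for f in features if f in seen or seen.add(f)})
        raise ValueError(f"{path}: duplicate feature id(s): {dupes[:5]}")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return pd.DataFrame(rows, index=pd.Index(features, name="feature"), columns=samples)


def write_expression(expr: pd.DataFrame, path) -> None:
    """Write a features x samples matrix as TSV at full precision."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature\t" + "\t".join(map(str, expr.columns)) + "\n")
        for feat, row in zip(expr.index, expr.to_numpy()):
            fh.write(str(feat) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical CSV; requires the documented sample_id/group columns."""
    clinical = pd.read_csv(path, dtype={"grade_group": "object"})
    missing = {"sample_id", "group"} - set(clinical.columns)
    if missing:
        raise ValueError(f"{path}: clinical table lacks columns {sorted(missing)}")
    if clinical["sample_id"].duplicated().any():
        dupes = clinical.loc[clinical["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id(s): {dupes[:5]}")
    return clinical


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (tab-separated: name, description, genes...)."""
    path = Path(path)
    sets = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, description, genes = parts[0], parts[1], tuple(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=genes, description=description))
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return sets


def write_gmt(sets, path) -> None:
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def read_signatures(path) -> list[SignatureModel]:
    """Read signature models from JSON: [{name, weights:{gene:w}, scale}]."""
    data = json.loads(Path(path).read_text())
    return [
        SignatureModel(name=d["name"], weights=d["weights"], scale=bool(d.get("scale", False)))
        for d in data
    ]


def write_signatures(sigs, path) -> None:
    payload = [{"name": s.name, "weights": dict(s.weights), "scale": s.scale} for s in sigs]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_drug_models(path) -> list[DrugResponseModel]:
    """Read drug models from JSON: [{drug, correlations:{gene: cor}}]."""
    data = json.loads(Path(path).read_text())
    return [
        DrugResponseModel(drug=d["drug"], gene_correlations=d["correlations"]) for d in data
    ]


def write_drug_models(models, path) -> None:
    payload = [{"drug": m.drug, "correlations": dict(m.gene_correlations)} for m in models]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_gene_panel(path) -> list[str]:
    """Read a one-gene-per-line panel file (or first set of a GMT)."""
    path = Path(path)
    first = path.read_text().splitlines()
    if first and "\t" in first[0]:
        return list(read_gmt(path)[0].genes)
    genes = [g.strip() for g in first if g.strip()]
    if not genes:
        raise ValueError(f"{path}: empty gene panel")
    return genes


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a scores x samples matrix as TSV."""
    write_expression(scores, path)


def align_to_clinical(expr: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Reorder expression columns to the clinical sample list.

    The clinical table is the master sample list; any mismatch between the
    two sample sets is a hard error (silent intersection hides label
    scrambling).
    """
    wanted = list(clinical["sample_id"])
    have = set(expr.columns)
    missing = [s for s in wanted if s not in have]
    extra = sorted(have - set(wanted))
    if missing or extra:
        raise ValueError(
            f"sample mismatch: {len(missing)} clinical sample(s) absent from expression "
            f"(e.g. {missing[:3]}), {len(extra)} expression column(s) not in clinical "
            f"(e.g. {extra[:3]})"
        )
    return expr[wanted]
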