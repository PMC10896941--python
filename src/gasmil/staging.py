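"""OLGA / OLGIM patient staging from five-site Sydney grades.

The updated Sydney protocol samples five gastric sites: two antrum
(lesser/greater curvature), the incisura angularis, and two corpus
(lesser/greater curvature). Atrophy (OLGA) and intestinal metaplasia
(OLGIM) grades 0-3 are first pooled into an antrum compartment score
(antrum sites + incisura) and a corpus compartment score, then the two
scores index a published 4x4 staging matrix giving stage 0-IV. Stages
III/IV identify the high gastric-cancer-risk group.

The staging matrices ship as CSV data files so the transcription from the
published systems is auditable; the default compartment pooling is the
arithmetic mean rounded half-up, with "max" available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

ANTRUM_SITES = ("antrum_lesser", "antrum_greater", "incisura")
CORPUS_SITES = ("corpus_lesser", "corpus_greater")
SITES = ANTRUM_SITES + CORPUS_SITES
FEATURES = ("inflammation", "activity", "atrophy", "IM")


class StagingError(ValueError):
    pass


@dataclass(frozen=True)
class SlideGrades:
    """Sydney grades 0-3 for the four features at one biopsy site."""

    inflammation: int
    activity: int
    atrophy: int
    IM: int

    def __post_init__(self):
        for f in FEATURES:
            g = getattr(self, f)
            if g not in (0, 1, 2, 3):
                raise StagingError(f"{f} grade {g} outside 0-3")


@dataclass
class PatientRecord:
    patient_id: str
    predictions: dict[str, SlideGrades]  # site -> grades

    def __post_init__(self):
        missing = set(SITES) - set(self.predictions)
        if missing:
            raise StagingError(f"patient {self.patient_id} missing sites: {sorted(missing)}")


@dataclass(frozen=True)
class StageResult:
    olga: int
    olgim: int
    compartment_scores: dict


def _load_matrix(name: str) -> np.ndarray:
    with resources.files("gasmil.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, comment="#", index_col=0)
    m = df.to_numpy(dtype=int)
    if m.shape != (4, 4):
        raise StagingError(f"staging matrix {name} must be 4x4")
    return m


_MATRICES = {
    "OLGA": _load_matrix("olga_matrix.csv"),
    "OLGIM": _load_matrix("olgim_matrix.csv"),
}


def compartment_score(site_grades: dict[str, int], compartment: str,
                      rule: str = "mean") -> int:
    """Pool one feature's site grades into a 0-3 compartment score.

    `rule="mean"` takes the arithmetic mean rounded half-up (default);
    `rule="max"` takes the worst site.
    """
    sites = {"antrum": ANTRUM_SITES, "corpus": CORPUS_SITES}.get(compartment)
    if sites is None:
        raise StagingError(f"unknown compartment {compartment!r}")
    missing = [s for s in sites if s not in site_grades]
    if missing:
        raise StagingError(f"missing site grades: {missing}")
    vals = [site_grades[s] for s in sites]
    for v in vals:
        if v not in (0, 1, 2, 3):
            raise StagingError(f"grade {v} outside 0-3")
    if rule == "mean":
        return int(math.floor(sum(vals) / len(vals) + 0.5))
    if rule == "max":
        return int(max(vals))
    raise StagingError(f"unknown pooling rule {rule!r}")


def stage_from_matrix(antrum_score: int, corpus_score: int, matrix: str) -> int:
    """Look up stage 0-4 in the published OLGA or OLGIM 4x4 matrix."""
    if matrix not in _MATRICES:
        raise StagingError(f"matrix must be OLGA or OLGIM, got {matrix!r}")
    if antrum_score not in (0, 1, 2, 3) or corpus_score not in (0, 1, 2, 3):
        raise StagingError("compartment scores must be in 0-3")
    return int(_MATRICES[matrix][antrum_score, corpus_score])


def stage_patient(record: PatientRecord, rule: str = "mean") -> StageResult:
    """OLGA from the atrophy compartment scores, OLGIM from the IM scores."""
    scores = {}
    for feature in FEATURES:
        site_grades = {s: getattr(g, feature) for s, g in record.predictions.items()}
        scores[feature] = {
            "antrum": compartment_score(site_grades, "antrum", rule),
            "corpus": compartment_score(site_grades, "corpus", rule),
        }
    olga = stage_from_matrix(scores["atrophy"]["antrum"], scores["atrophy"]["corpus"], "OLGA")
    olgim = stage_from_matrix(scores["IM"]["antrum"], scores["IM"]["corpus"], "OLGIM")
    return StageResult(olga=olga, olgim=olgim, compartment_scores=scores)


# -- tabular I/O ---------------------------------------------------------


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Build PatientRecords from long-format rows (patient_id, site, feature, grade)."""
    records = []
    for pid, g in df.groupby("patient_id", sort=True):
        preds = {}
        for site, gs in g.groupby("site"):
            kv = dict(zip(gs["feature"], gs["grade"].astype(int)))
            preds[site] = SlideGrades(**{f: kv[f] for f in FEATURES})
        records.append(PatientRecord(str(pid), preds))
    return records


def stage_frame(df: pd.DataFrame, rule: str = "mean") -> pd.DataFrame:
    """Stage every patient in a long-format grade table; returns one row each."""
    rows = []
    for rec in records_from_frame(df):
        res = stage_patient(rec, rule)
        rows.append({"patient_id": rec.patient_id, "olga": res.olga, "olgim": res.olgim})
    return pd.DataFrame(rows)
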