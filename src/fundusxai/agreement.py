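"""Cohen's kappa agreement between manual and automatic lesion indicators.

For each (method, DR grade, prediction correctness, lesion type)
stratum, the manual rater says whether they saw the heatmap highlight
that lesion in each image, and the automatic rater is the overlap
pipeline's hit flag.  Kappa corrects the observed agreement for
chance:

    kappa = (p_o - p_e) / (1 - p_e),   p_e = sum_c p_A(c) * p_B(c)

Edge conventions follow the reporting style of agreement tables in
this domain: a stratum with no images renders as a dash; kappa is
undefined (N/A) when the chance agreement p_e equals 1, i.e. both
raters are constant on the same category.  When exactly one rater is
constant, p_o = p_e < 1 and kappa is exactly 0.  When both raters are
constant but on *different* categories, p_e = 0 and kappa = 0 — this
is a genuine (total) disagreement, not an undefined case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NA",
    "DASH",
    "RaterVector",
    "AgreementCell",
    "cohens_kappa",
    "kappa_from_table",
    "build_agreement_table",
    "render_agreement_table",
]

NA = "N/A"
DASH = "-"


@dataclass
class RaterVector:
    """Ordered binary judgments of one rater over a list of images."""

    image_ids: Sequence[str]
    labels: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.image_ids) != len(self.labels):
            raise ValueError("image_ids and labels must have equal length")


@dataclass
class AgreementCell:
    """One kappa cell: a value in [-1, 1], or NA/DASH, with stratum size."""

    value: float | str
    n: int

    def render(self) -> str:
        if isinstance(self.value, str):
            return self.value
        return f"{self.value:.4f}"


def kappa_from_table(a: int, b: int, c: int, d: int) -> AgreementCell:
    """Kappa from the 2x2 joint table.

    a = both positive, b = A-only positive, c = B-only positive,
    d = both negative.
    """
    n = a + b + c + d
    if n == 0:
        return AgreementCell(DASH, 0)
    po = (a + d) / n
    pa_pos = (a + b) / n
    pb_pos = (a + c) / n
    pe = pa_pos * pb_pos + (1 - pa_pos) * (1 - pb_pos)
    if pe == 1.0:
        return AgreementCell(NA, n)
    return AgreementCell((po - pe) / (1 - pe), n)


def cohens_kappa(rater_a: RaterVector, rater_b: RaterVector) -> AgreementCell:
    """Cohen's kappa between two binary raters over the same image set."""
    if list(rater_a.image_ids) != list(rater_b.image_ids):
        raise ValueError("raters must cover the same images in the same order")
    la = np.asarray(rater_a.labels, dtype=int)
    lb = np.asarray(rater_b.labels, dtype=int)
    a = int(np.sum((la == 1) & (lb == 1)))
    b = int(np.sum((la == 1) & (lb == 0)))
    c = int(np.sum((la == 0) & (lb == 1)))
    d = int(np.sum((la == 0) & (lb == 0)))
    return kappa_from_table(a, b, c, d)


def build_agreement_table(
    manual: pd.DataFrame,
    automatic: pd.DataFrame,
    lesions: Sequence[str],
    methods: Sequence[str] = ("gradcam", "ig"),
) -> pd.DataFrame:
    """Kappa per (method, grade, correctness, lesion) stratum.

    ``manual`` has columns image_id, method, lesion, highlighted (0/1);
    ``automatic`` is the overlap-record frame (image_id, method,
    lesion, grade, correct, hit).  Both must cover the same images.
    Returns a long frame with columns method, grade, correct, lesion,
    kappa (string: 4-decimal value, 'N/A', or '-'), n.
    """
    auto_ids = set(automatic["image_id"])
    man_ids = set(manual["image_id"])
    if auto_ids != man_ids:
        only_m = sorted(man_ids - auto_ids)
        only_a = sorted(auto_ids - man_ids)
        raise ValueError(
            f"image sets differ: manual-only {only_m}, automatic-only {only_a}"
        )
    strata = automatic[["image_id", "grade", "correct"]].drop_duplicates("image_id")
    rows = []
    for method in methods:
        man_m = manual[manual["method"] == method]
        auto_m = automatic[automatic["method"] == method]
        for grade in sorted(strata["grade"].unique()):
            for correct in (True, False):
                ids = sorted(
                    strata[(strata["grade"] == grade) & (strata["correct"] == correct)][
                        "image_id"
                    ]
                )
                for lesion in lesions:
                    if not ids:
                        cell = AgreementCell(DASH, 0)
                    else:
                        man_lookup = man_m[man_m["lesion"] == lesion].set_index(
                            "image_id"
                        )["highlighted"]
                        auto_lookup = auto_m[auto_m["lesion"] == lesion].set_index(
                            "image_id"
                        )["hit"]
                        va = RaterVector(ids, [int(man_lookup.get(i, 0)) for i in ids])
                        vb = RaterVector(ids, [int(auto_lookup.get(i, 0)) for i in ids])
                        cell = cohens_kappa(va, vb)
                    rows.append(
                        {
                            "method": method,
                            "grade": int(grade),
                            "correct": correct,
                            "lesion": lesion,
                            "kappa": cell.render(),
                            "n": cell.n,
                        }
                    )
    return pd.DataFrame(rows)


def render_agreement_table(table: pd.DataFrame, lesions: Sequence[str]) -> pd.DataFrame:
    """Wide rendering: one row per (method, grade); per-lesion kappa
    columns under correct then incorrect prediction."""
    rows = []
    for (method, grade), g in table.groupby(["method", "grade"], sort=True):
        row: dict = {"method": method, "grade": grade}
        for correct, tag in ((True, "correct"), (False, "incorrect")):
            sub = g[g["correct"] == correct].set_index("lesion")["kappa"]
            for lesion in lesions:
                row[f"{tag}_{lesion}"] = sub.get(lesion, DASH)
        rows.append(row)
    return pd.DataFrame(rows)
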