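"""Diagnostic-code indicator matrices, code filters and the dataset split.

Per-patient code sets become a patients × codes binary matrix.  Before any
sex-association screening, codes that are present in at most one person in
either the training or the validation set, or whose carriers are all of one
sex in either set, are removed from both sets — the latter guards the
downstream univariate logistic screen against complete separation and keeps
the derived gender characteristics relevant to both sexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def normalize_code(code: str) -> str:
    """Codes compare as exact strings after uppercasing and stripping
    whitespace and dots; no truncation to 3-character blocks."""
    return str(code).strip().upper().replace(".", "").replace(" ", "")


@dataclass
class CodeIndicatorMatrix:
    """Binary presence indicators, one row per patient, one column per
    distinct diagnostic code, with the aligned sex vector (female = 1)."""

    patient_ids: list
    code_labels: list
    indicators: np.ndarray  # (n_patients, n_codes), int8 in {0, 1}
    sex: np.ndarray

    def __post_init__(self):
        self.indicators = np.asarray(self.indicators, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=int)
        if self.indicators.shape != (len(self.patient_ids), len(self.code_labels)):
            raise ValueError("indicator matrix shape does not match labels")
        if len(self.sex) != len(self.patient_ids):
            raise ValueError("sex vector length mismatch")
        if len(set(self.code_labels)) != len(self.code_labels):
            raise ValueError("duplicate code labels")

    @property
    def shape(self):
        return self.indicators.shape

    def restrict(self, labels) -> "CodeIndicatorMatrix":
        """Columns for ``labels`` in the given order; codes absent from this
        matrix come back as all-zero columns."""
        pos = {c: j for j, c in enumerate(self.code_labels)}
        n = len(self.patient_ids)
        cols = np.zeros((n, len(labels)), dtype=np.int8)
        for k, lab in enumerate(labels):
            j = pos.get(lab)
            if j is not None:
                cols[:, k] = self.indicators[:, j]
        return CodeIndicatorMatrix(self.patient_ids, list(labels), cols, self.sex)


@dataclass
class CodeFilterReport:
    removed_singleton: list
    removed_sex_exclusive: list
    retained: list


def build_indicator_matrix(cohort: pd.DataFrame) -> CodeIndicatorMatrix:
    """Cell (i, j) is 1 iff patient i's code set contains label j; a code
    repeated within one visit still yields 1 (set semantics).  Labels are
    normalized and sorted."""
    code_sets = [frozenset(normalize_code(c) for c in row)
                 for row in cohort["codes"]]
    labels = sorted(set().union(*code_sets)) if code_sets else []
    pos = {c: j for j, c in enumerate(labels)}
    ind = np.zeros((len(code_sets), len(labels)), dtype=np.int8)
    for i, s in enumerate(code_sets):
        for c in s:
            ind[i, pos[c]] = 1
    return CodeIndicatorMatrix(list(cohort["patient_id"]), labels, ind,
                               cohort["sex"].to_numpy())


def _align(m: CodeIndicatorMatrix, labels) -> CodeIndicatorMatrix:
    return m.restrict(labels)


def filter_codes(train: CodeIndicatorMatrix, validation: CodeIndicatorMatrix,
                 rule: str = "either",
                 ) -> tuple[CodeIndicatorMatrix, CodeIndicatorMatrix, CodeFilterReport]:
    """Remove uncommon and sex-exclusive codes from both sets.

    Over the union vocabulary, a code is dropped as a singleton if its
    carrier count is <= 1 in either set (``rule="either"``, the default) or
    in the pooled data (``rule="pooled"``); a remaining code is dropped as
    sex-exclusive if all its carriers are one sex under the same rule.  Both
    returned matrices share the retained vocabulary, label-sorted.
    """
    if rule not in ("either", "pooled"):
        raise ValueError("rule must be 'either' or 'pooled'")
    universe = sorted(set(train.code_labels) | set(validation.code_labels))
    tr = _align(train, universe)
    va = _align(validation, universe)

    def counts(m):
        fem = m.sex == 1
        total = m.indicators.sum(axis=0)
        f = m.indicators[fem].sum(axis=0)
        return total, f, total - f

    t_tot, t_f, t_m = counts(tr)
    v_tot, v_f, v_m = counts(va)
    if rule == "either":
        singleton = (t_tot <= 1) | (v_tot <= 1)
        exclusive = (~singleton) & (((t_f == 0) | (t_m == 0))
                                    | ((v_f == 0) | (v_m == 0)))
    else:
        singleton = (t_tot + v_tot) <= 1
        exclusive = (~singleton) & (((t_f + v_f) == 0) | ((t_m + v_m) == 0))

    labels = np.array(universe)
    retained = list(labels[~(singleton | exclusive)])
    report = CodeFilterReport(
        removed_singleton=list(labels[singleton]),
        removed_sex_exclusive=list(labels[exclusive]),
        retained=retained,
    )
    return tr.restrict(retained), va.restrict(retained), report


def split_dataset(cohort: pd.DataFrame,
                  fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
                  seed: int = 0):
    """Random patient-level partition into (train, validation, test).

    Sizes follow largest-remainder rounding of ``n × fraction`` (ties broken
    by position); the partition is disjoint, exhaustive and deterministic
    given ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(cohort)
    exact = np.array([n * f for f in fractions])
    sizes = np.floor(exact).astype(int)
    rem = exact - sizes
    for k in np.argsort(-rem, kind="stable")[: n - sizes.sum()]:
        sizes[k] += 1
    perm = np.random.default_rng(seed).permutation(n)
    bounds = np.cumsum(sizes)[:-1]
    parts = np.split(perm, bounds)
    return tuple(cohort.iloc[np.sort(p)].reset_index(drop=True) for p in parts)


def export_matrix(m: CodeIndicatorMatrix, prefix: str) -> None:
    """Sparse on-disk export: MatrixMarket file plus label sidecars."""
    from scipy import io as sio
    from scipy import sparse

    sio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(m.indicators))
    with open(f"{prefix}.codes.txt", "w") as fh:
        fh.write("\n".join(m.code_labels) + ("\n" if m.code_labels else ""))
    with open(f"{prefix}.patients.txt", "w") as fh:
        fh.write("\n".join(str(p) for p in m.patient_ids)
                 + ("\n" if m.patient_ids else ""))
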