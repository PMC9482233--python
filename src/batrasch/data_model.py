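"""Scale specification, response matrices, complete-case filtering, sampling.

External response files code categories ``min_code..max_code`` (1..5 for the
BAT); internally every item is 0-based (``0..m_i``) because the partial
credit model indexes categories from zero. Missing responses are represented
(as ``-1`` in the integer grid) but every estimation routine downstream
requires complete data — filtering is an explicit, reported step.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import bat

MISSING = -1


class FormatError(ValueError):
    """A response file does not match the scale specification."""


@dataclasses.dataclass(frozen=True)
class ScaleSpec:
    """Item identifiers, subscale membership and category counts of a scale."""

    items: tuple[str, ...]
    subscale_of: dict[str, str]
    n_categories: dict[str, int]
    min_code: int = 1
    max_code: int = 5

    def __post_init__(self) -> None:
        for item in self.items:
            if item not in self.subscale_of:
                raise ValueError(f"item {item!r} has no subscale")
            m = self.n_categories.get(item)
            if m is None or m < 2:
                raise ValueError(f"item {item!r} needs >= 2 categories")

    @property
    def subscales(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for item in self.items:
            seen.setdefault(self.subscale_of[item], None)
        return tuple(seen)

    def items_of(self, subscale: str) -> tuple[str, ...]:
        return tuple(i for i in self.items if self.subscale_of[i] == subscale)

    def max_internal(self, item: str) -> int:
        """Highest internal code m_i for an item (categories are 0..m_i)."""
        return self.n_categories[item] - 1

    @classmethod
    def from_config(cls, path: str | Path) -> "ScaleSpec":
        """Read a scale spec from a JSON or YAML config file."""
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(
            items=tuple(raw["items"]),
            subscale_of=dict(raw["subscale_of"]),
            n_categories={k: int(v) for k, v in raw["n_categories"].items()},
            min_code=int(raw.get("min_code", 1)),
            max_code=int(raw.get("max_code", 5)),
        )


def bat_spec() -> ScaleSpec:
    """The bundled 23-item BAT specification (EX=8, MD=5, CI=5, EI=5)."""
    return ScaleSpec(
        items=tuple(bat.BAT_ITEMS),
        subscale_of={i: s for s, its in bat.BAT_SUBSCALES.items() for i in its},
        n_categories={i: 5 for i in bat.BAT_ITEMS},
        min_code=bat.BAT_MIN_CODE,
        max_code=bat.BAT_MAX_CODE,
    )


@dataclasses.dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with optional per-person covariates.

    ``responses`` holds internal 0-based codes with ``MISSING`` (=-1) marking
    absent answers; column order matches ``spec.items``.
    """

    spec: ScaleSpec
    responses: np.ndarray  # (n_persons, n_items) int
    person_ids: np.ndarray  # (n_persons,) — arbitrary labels
    covariates: pd.DataFrame | None = None  # indexed 0..n-1, e.g. "age", "group"

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=int)
        if self.responses.ndim != 2 or self.responses.shape[1] != len(self.spec.items):
            raise ValueError("responses must be persons x items for the spec")
        self.person_ids = np.asarray(self.person_ids)
        if len(self.person_ids) != self.responses.shape[0]:
            raise ValueError("person_ids length mismatch")
        for j, item in enumerate(self.spec.items):
            col = self.responses[:, j]
            ok = (col == MISSING) | ((col >= 0) & (col <= self.spec.max_internal(item)))
            if not ok.all():
                bad = int(np.flatnonzero(~ok)[0])
                raise ValueError(
                    f"response out of range for item {item!r} at row {bad}: {col[bad]}"
                )
        if self.covariates is not None and len(self.covariates) != self.n_persons:
            raise ValueError("covariates length mismatch")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def is_missing(self) -> np.ndarray:
        return self.responses == MISSING

    def max_scores(self) -> np.ndarray:
        """Per-item maximum internal code m_i."""
        return np.array([self.spec.max_internal(i) for i in self.spec.items])

    def total_scores(self) -> np.ndarray:
        """Raw total scores (internal codes); requires complete data."""
        if self.is_missing().any():
            raise ValueError("total scores require complete data")
        return self.responses.sum(axis=1)

    def subset_items(self, items: list[str]) -> "ResponseMatrix":
        """Restrict to a subset of items (order follows the current spec)."""
        keep = [i for i in self.spec.items if i in set(items)]
        idx = [self.spec.items.index(i) for i in keep]
        sub = ScaleSpec(
            items=tuple(keep),
            subscale_of={i: self.spec.subscale_of[i] for i in keep},
            n_categories={i: self.spec.n_categories[i] for i in keep},
            min_code=self.spec.min_code,
            max_code=self.spec.max_code,
        )
        return ResponseMatrix(sub, self.responses[:, idx].copy(),
                              self.person_ids.copy(),
                              None if self.covariates is None
                              else self.covariates.reset_index(drop=True))

    def take(self, rows: np.ndarray) -> "ResponseMatrix":
        rows = np.asarray(rows)
        return ResponseMatrix(
            self.spec,
            self.responses[rows],
            self.person_ids[rows],
            None if self.covariates is None
            else self.covariates.iloc[rows].reset_index(drop=True),
        )


@dataclasses.dataclass
class ExclusionReport:
    """Tally of persons removed by the complete-case rules, in rule order."""

    n_input: int
    all_missing: int
    missing_by_count: dict[int, int]  # e.g. {1: 20, 2: 1, 3: 2} (3 = "3 or more")
    missing_covariate: int
    n_retained: int

    def total_excluded(self) -> int:
        return self.all_missing + sum(self.missing_by_count.values()) + self.missing_covariate


def load_responses(path: str | Path, spec: ScaleSpec) -> ResponseMatrix:
    """Read a CSV response file (one row per respondent) into internal codes.

    The file must contain one column per item of ``spec``; empty cells are
    missing; any other non-integer or out-of-range cell raises with the
    offending row and column named.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for item in spec.items:
        if item not in df.columns:
            raise FormatError(f"missing item column {item!r}")
    n = len(df)
    resp = np.full((n, len(spec.items)), MISSING, dtype=int)
    for j, item in enumerate(spec.items):
        for r, cell in enumerate(df[item].str.strip()):
            if cell == "":
                continue
            try:
                v = int(cell)
            except ValueError:
                raise FormatError(
                    f"non-integer response {cell!r} at row {r}, item {item!r}"
                ) from None
            hi = spec.min_code + spec.max_internal(item)
            if not spec.min_code <= v <= hi:
                raise FormatError(
                    f"response {v} out of range [{spec.min_code}, {hi}] "
                    f"at row {r}, item {item!r}"
                )
            resp[r, j] = v - spec.min_code
    ids = (df["person_id"].to_numpy() if "person_id" in df.columns
           else np.arange(n))
    cov_cols = [c for c in df.columns if c not in spec.items and c != "person_id"]
    cov = None
    if cov_cols:
        cov = df[cov_cols].replace("", np.nan).reset_index(drop=True)
        for c in cov_cols:
            num = pd.to_numeric(cov[c], errors="coerce")
            if num.isna().equals(cov[c].isna()):  # fully numeric column
                cov[c] = num
    return ResponseMatrix(spec, resp, ids, cov)


def write_responses(rm: ResponseMatrix, path: str | Path) -> None:
    """Write a ResponseMatrix back to CSV in external coding (round-trips)."""
    out = {}
    out["person_id"] = rm.person_ids
    for j, item in enumerate(rm.spec.items):
        col = rm.responses[:, j].astype(object)
        ext = [("" if v == MISSING else str(v + rm.spec.min_code)) for v in col]
        out[item] = ext
    df = pd.DataFrame(out)
    if rm.covariates is not None:
        for c in rm.covariates.columns:
            df[c] = rm.covariates[c].to_numpy()
    df.to_csv(path, index=False)


def filter_complete_cases(
    rm: ResponseMatrix, required_covariates: list[str] | None = None
) -> tuple[ResponseMatrix, ExclusionReport]:
    """Keep persons with no missing item response and no missing covariate.

    Exclusions are tallied in order: all items missing first, then partial
    missingness by count (1, 2, 3-or-more), then missing covariate among the
    remaining. Idempotent.
    """
    required_covariates = required_covariates or []
    miss = rm.is_missing()
    n_miss = miss.sum(axis=1)
    k = rm.n_items
    all_missing = n_miss == k
    by_count = {c: ((n_miss == c) if c < 3 else ((n_miss >= 3) & ~all_missing))
                for c in (1, 2, 3)}
    item_complete = n_miss == 0
    cov_missing = np.zeros(rm.n_persons, dtype=bool)
    for c in required_covariates:
        if rm.covariates is None or c not in rm.covariates.columns:
            cov_missing |= True
        else:
            cov_missing |= rm.covariates[c].isna().to_numpy()
    keep = item_complete & ~cov_missing
    report = ExclusionReport(
        n_input=rm.n_persons,
        all_missing=int(all_missing.sum()),
        missing_by_count={c: int(m.sum()) for c, m in by_count.items()},
        missing_covariate=int((item_complete & cov_missing).sum()),
        n_retained=int(keep.sum()),
    )
    return rm.take(np.flatnonzero(keep)), report


def split_random_samples(
    rm: ResponseMatrix, sizes: list[int], seed: int
) -> list[ResponseMatrix]:
    """Draw disjoint random samples of the given sizes without replacement."""
    total = sum(sizes)
    if total > rm.n_persons:
        raise ValueError(f"requested {total} persons but only {rm.n_persons} available")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(rm.n_persons)
    out, start = [], 0
    for s in sizes:
        out.append(rm.take(np.sort(perm[start:start + s])))
        start += s
    return out


def median_age_groups(
    ages: np.ndarray, split: float | None = None, ties: str = "lower"
) -> tuple[np.ndarray, float]:
    """Median split into 'younger'/'older'; ties go to the lower group by default."""
    ages = np.asarray(ages, dtype=float)
    cut = float(np.median(ages)) if split is None else float(split)
    if ties == "lower":
        younger = ages <= cut
    else:
        younger = ages < cut
    labels = np.where(younger, "younger", "older")
    return labels, cut
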