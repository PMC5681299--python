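"""Carrier cohort data model, file I/O and assembly rules.

A cohort is a flat list of mutation carriers, one record per at-risk carrier,
grouped into families.  Assembly follows registry conventions: EPCAM-deletion
families are analysed with the MSH2 families (the deletion silences MSH2),
dual MLH1+PMS2 families are analysed as PMS2, carriers with two carrier
parents / unknown sex / missing follow-up age are excluded, and each
carrier's generation is coded as depth below the oldest observed generation
of their family (oldest = 0).
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("anticipation")

#: analysis gene categories, in the fixed reporting order (MLH1 = reference)
GENES = ("MLH1", "MSH2", "MSH6", "PMS2")

#: recognised raw (pre-grouping) gene labels
RAW_GENES = ("MLH1", "MSH2", "MSH6", "PMS2", "MLH1+PMS2", "EPCAM")

SEXES = ("male", "female", "unknown")


class SchemaError(ValueError):
    """Input file does not conform to the cohort schema."""


class IntegrityError(ValueError):
    """Input violates a uniqueness or consistency constraint."""


class PedigreeError(ValueError):
    """Parent links do not form a usable pedigree."""


class EstimationError(RuntimeError):
    """A model fit could not be carried out on the given cohort."""


@dataclass
class CarrierRecord:
    """One at-risk mutation carrier.

    ``age`` is the age at first Lynch-associated diagnosis when ``event`` is
    True, otherwise the age at last follow-up; it may be missing (None) on
    ingest but not after exclusion filtering.
    """

    family_id: str
    person_id: str
    sex: str = "unknown"
    raw_gene: str = "MLH1"
    generation_depth: int | None = None
    mother_id: str | None = None
    father_id: str | None = None
    age: float | None = None
    event: bool = False
    n_diagnoses: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.raw_gene not in RAW_GENES:
            raise ValueError(f"unrecognized gene label {self.raw_gene!r}")

    @property
    def gene_category(self) -> str:
        return assign_gene_category(self.raw_gene)


@dataclass
class FamilyRecord:
    """Family-level view: analysis gene category and sizes."""

    family_id: str
    gene_category: str
    n_carriers: int
    n_generations: int


@dataclass
class DesignRow:
    """Per-carrier regression inputs.

    ``Z`` is the generation covariate, ``X`` the fixed covariate 4-vector
    (male, MSH2, MSH6, PMS2 indicators; MLH1 is the reference category) and
    ``Zstar`` the gene-generation interaction 4-vector Z * 1[gene = g] over
    (MLH1, MSH2, MSH6, PMS2).
    """

    Z: int
    X: tuple[float, float, float, float]
    Zstar: tuple[float, float, float, float]


@dataclass
class ExclusionLog:
    """Counts of carriers dropped by the exclusion cascade, by reason."""

    counts: dict[str, int] = field(
        default_factory=lambda: {
            "dual_carrier_parents": 0,
            "unknown_sex": 0,
            "missing_age": 0,
        }
    )
    retained: int = 0

    @property
    def intake(self) -> int:
        return self.retained + sum(self.counts.values())


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_COLUMNS = (
    "family_id",
    "person_id",
    "sex",
    "gene",
    "generation",
    "mother_id",
    "father_id",
    "age",
    "event",
    "n_diagnoses",
)
_REQUIRED = ("family_id", "person_id", "sex", "gene", "age", "event")
_MISSING = ("", "NA", "NaN", "nan", "None")


def _parse_cell(text: str) -> str | None:
    text = text.strip()
    return None if text in _MISSING else text


def read_cohort(path) -> list[CarrierRecord]:
    """Read a delimited-text cohort file (comma default, tab accepted).

    Raises :class:`SchemaError` when a required column is absent or rows are
    malformed (reported with their line numbers), :class:`IntegrityError`
    on duplicate ``(family_id, person_id)`` pairs.
    """
    with open(path, newline="") as fh:
        sample = fh.readline()
        delim = "\t" if sample.count("\t") >= sample.count(",") and "\t" in sample else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing_cols = [c for c in _REQUIRED if c not in header]
        if missing_cols:
            raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")

        records: list[CarrierRecord] = []
        problems: list[str] = []
        seen: set[tuple[str, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            cells = {k: _parse_cell(v if v is not None else "") for k, v in row.items() if k}
            try:
                records.append(_record_from_cells(cells))
            except (ValueError, TypeError) as exc:
                problems.append(f"line {lineno}: {exc}")
                continue
            key = (records[-1].family_id, records[-1].person_id)
            if key in seen:
                raise IntegrityError(
                    f"line {lineno}: duplicate (family_id, person_id) = {key}"
                )
            seen.add(key)
        if problems:
            raise SchemaError("malformed rows:\n" + "\n".join(problems))
    return records


def _record_from_cells(cells: Mapping[str, str | None]) -> CarrierRecord:
    fam = cells.get("family_id")
    pid = cells.get("person_id")
    if fam is None or pid is None:
        raise ValueError("family_id and person_id are required")
    sex = (cells.get("sex") or "unknown").lower()
    gene = cells.get("gene")
    if gene is None:
        raise ValueError("gene is required")
    gen = cells.get("generation")
    age = cells.get("age")
    event = cells.get("event")
    if event is None:
        raise ValueError("event is required")
    if event not in ("0", "1"):
        raise ValueError(f"event must be 0 or 1, got {event!r}")
    ndiag = cells.get("n_diagnoses")
    return CarrierRecord(
        family_id=fam,
        person_id=pid,
        sex=sex,
        raw_gene=gene,
        generation_depth=int(gen) if gen is not None else None,
        mother_id=cells.get("mother_id"),
        father_id=cells.get("father_id"),
        age=float(age) if age is not None else None,
        event=event == "1",
        n_diagnoses=int(ndiag) if ndiag is not None else None,
    )


def write_cohort(cohort: Sequence[CarrierRecord], path, delimiter: str = ",") -> None:
    """Write a cohort back to delimited text (round-trips with read_cohort)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_COLUMNS)
        for rec in cohort:
            writer.writerow(
                [
                    rec.family_id,
                    rec.person_id,
                    rec.sex,
                    rec.raw_gene,
                    "" if rec.generation_depth is None else rec.generation_depth,
                    rec.mother_id or "",
                    rec.father_id or "",
                    "" if rec.age is None else repr(float(rec.age)),
                    int(rec.event),
                    "" if rec.n_diagnoses is None else rec.n_diagnoses,
                ]
            )


# ---------------------------------------------------------------------------
# assembly rules
# ---------------------------------------------------------------------------

def assign_gene_category(raw_gene: str) -> str:
    """Map a raw gene label to its analysis category.

    EPCAM-deletion families are grouped with MSH2 (the deletion silences
    MSH2 expression); dual MLH1+PMS2 families are counted as PMS2.
    """
    if raw_gene not in RAW_GENES:
        raise ValueError(f"unrecognized gene label {raw_gene!r}")
    if raw_gene == "EPCAM":
        return "MSH2"
    if raw_gene == "MLH1+PMS2":
        return "PMS2"
    return raw_gene


def apply_exclusions(
    carriers: Sequence[CarrierRecord],
) -> tuple[list[CarrierRecord], ExclusionLog]:
    """Apply the exclusion cascade, in its fixed order.

    1. carriers whose mother *and* father are both carriers in the same family
    2. carriers of unknown sex
    3. carriers with missing age (diagnosis age if an event, otherwise age at
       last follow-up — both are required by the likelihoods)

    Returns the retained carriers and a log of counts by reason.
    """
    log = ExclusionLog()
    by_family: dict[str, set[str]] = {}
    for rec in carriers:
        by_family.setdefault(rec.family_id, set()).add(rec.person_id)

    retained: list[CarrierRecord] = []
    for rec in carriers:
        members = by_family[rec.family_id]
        if (
            rec.mother_id is not None
            and rec.father_id is not None
            and rec.mother_id in members
            and rec.father_id in members
        ):
            log.counts["dual_carrier_parents"] += 1
        elif rec.sex == "unknown":
            log.counts["unknown_sex"] += 1
        elif rec.age is None:
            log.counts["missing_age"] += 1
        else:
            retained.append(rec)
    log.retained = len(retained)
    return retained, log


def code_generations(carriers: Sequence[CarrierRecord]) -> list[CarrierRecord]:
    """Assign each carrier's generation depth below the oldest observed
    generation of its family (oldest = 0).

    When parent links are present, depth is the number of carrier-to-carrier
    parent steps from the family's founder carriers (carriers with no carrier
    parent in the family); with two carrier parents the deeper one counts.
    An explicitly supplied ``generation_depth`` wins over the link-derived
    value, with a logged warning on inconsistency.  Depths are normalised so
    every family's minimum is 0.
    """
    out: list[CarrierRecord] = []
    for fam_id, fam in _group_by_family(carriers).items():
        derived = _depths_from_links(fam_id, fam)
        depths: list[int] = []
        for rec in fam:
            if rec.generation_depth is not None:
                if derived is not None and derived[rec.person_id] != rec.generation_depth:
                    logger.warning(
                        "family %s person %s: explicit generation %d disagrees with "
                        "pedigree-derived depth %d; keeping the explicit value",
                        fam_id, rec.person_id, rec.generation_depth, derived[rec.person_id],
                    )
                depths.append(rec.generation_depth)
            elif derived is not None:
                depths.append(derived[rec.person_id])
            else:
                raise PedigreeError(
                    f"family {fam_id} person {rec.person_id}: no explicit generation "
                    "and no parent links to derive one from"
                )
        base = min(depths)
        out.extend(replace(r, generation_depth=d - base) for r, d in zip(fam, depths))
    return out


def _group_by_family(carriers: Iterable[CarrierRecord]) -> dict[str, list[CarrierRecord]]:
    fams: dict[str, list[CarrierRecord]] = {}
    for rec in carriers:
        fams.setdefault(rec.family_id, []).append(rec)
    return fams


def _depths_from_links(fam_id: str, fam: Sequence[CarrierRecord]) -> dict[str, int] | None:
    members = {rec.person_id: rec for rec in fam}
    if not any(
        (r.mother_id in members) or (r.father_id in members) for r in fam
    ):
        if all(r.generation_depth is not None for r in fam):
            return None  # explicit depths stand on their own
        # no intra-family links: every carrier is a founder (depth 0)
        return {r.person_id: 0 for r in fam}

    depths: dict[str, int] = {}
    state: dict[str, int] = {}  # 1 = on stack, 2 = done

    def resolve(pid: str) -> int:
        if pid in depths:
            return depths[pid]
        if state.get(pid) == 1:
            raise PedigreeError(f"family {fam_id}: cycle in parent links at {pid}")
        state[pid] = 1
        rec = members[pid]
        parents = [p for p in (rec.mother_id, rec.father_id) if p in members]
        d = 0 if not parents else max(resolve(p) for p in parents) + 1
        depths[pid] = d
        state[pid] = 2
        return d

    for pid in members:
        resolve(pid)
    return depths


def family_records(carriers: Sequence[CarrierRecord]) -> list[FamilyRecord]:
    """Family-level view of an assembled cohort (gene category must be
    constant within each family)."""
    out = []
    for fam_id, fam in _group_by_family(carriers).items():
        cats = {rec.gene_category for rec in fam}
        if len(cats) > 1:
            raise IntegrityError(
                f"family {fam_id} has inconsistent gene categories {sorted(cats)}"
            )
        gens = [rec.generation_depth for rec in fam]
        if any(g is None for g in gens):
            raise IntegrityError(f"family {fam_id} has uncoded generations")
        out.append(
            FamilyRecord(
                family_id=fam_id,
                gene_category=cats.pop(),
                n_carriers=len(fam),
                n_generations=int(max(gens)) + 1,  # type: ignore[arg-type]
            )
        )
    return out


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(carriers: Sequence[CarrierRecord]) -> list[DesignRow]:
    """Build per-carrier regression rows aligned 1:1 with ``carriers``.

    X = (1[male], 1[MSH2], 1[MSH6], 1[PMS2]) with MLH1 as reference;
    Zstar = Z * (1[MLH1], 1[MSH2], 1[MSH6], 1[PMS2]).
    """
    rows = []
    for rec in carriers:
        if rec.sex == "unknown":
            raise IntegrityError(
                f"carrier {rec.family_id}/{rec.person_id} with unknown sex reached "
                "design construction; apply_exclusions first"
            )
        if rec.generation_depth is None:
            raise IntegrityError(
                f"carrier {rec.family_id}/{rec.person_id} has no generation depth; "
                "code_generations first"
            )
        gene = rec.gene_category
        z = int(rec.generation_depth)
        x = (
            1.0 if rec.sex == "male" else 0.0,
            1.0 if gene == "MSH2" else 0.0,
            1.0 if gene == "MSH6" else 0.0,
            1.0 if gene == "PMS2" else 0.0,
        )
        zstar = tuple(float(z) * float(gene == g) for g in GENES)
        rows.append(DesignRow(Z=z, X=x, Zstar=zstar))  # type: ignore[arg-type]
    return rows


def design_arrays(
    cohort: Sequence[CarrierRecord],
    design: Sequence[DesignRow],
    interactions: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Flatten cohort + design into the arrays the fitters consume.

    Returns ``(age, event, family_index, Zmat, X, family_ids)`` with
    ``Zmat`` of shape (n, 1) (scalar generation covariate) or (n, 4)
    (gene-generation interaction vector).
    """
    if len(cohort) != len(design):
        raise ValueError("cohort and design are not aligned")
    age = np.array([rec.age for rec in cohort], dtype=float)
    if np.isnan(age).any():
        raise IntegrityError("missing ages reached model fitting")
    event = np.array([rec.event for rec in cohort], dtype=bool)
    fam_ids = sorted({rec.family_id for rec in cohort})
    fam_pos = {f: i for i, f in enumerate(fam_ids)}
    fam_idx = np.array([fam_pos[rec.family_id] for rec in cohort], dtype=np.intp)
    if interactions:
        zmat = np.array([row.Zstar for row in design], dtype=float)
    else:
        zmat = np.array([[row.Z] for row in design], dtype=float)
    x = np.array([row.X for row in design], dtype=float)
    return age, event, fam_idx, zmat, x, fam_ids


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------

def summarize_cohort(carriers: Sequence[CarrierRecord]) -> pd.DataFrame:
    """Registry-style descriptive table, per gene category and overall.

    Means are reported to one decimal; medians of onset age and follow-up
    come from (reverse) Kaplan-Meier estimation.  Columns are "All" plus the
    gene categories present.
    """
    from .km import km_estimate, km_median, median_followup

    fams = family_records(carriers)
    cols: dict[str, pd.Series] = {}
    groups = [("All", None)] + [(g, g) for g in GENES]
    for label, gene in groups:
        sub = [r for r in carriers if gene is None or r.gene_category == gene]
        if not sub:
            continue
        subfams = [f for f in fams if gene is None or f.gene_category == gene]
        ages = np.array([r.age for r in sub], dtype=float)
        events = np.array([r.event for r in sub], dtype=bool)
        ndiag = sum(
            (r.n_diagnoses if r.n_diagnoses is not None else int(r.event)) for r in sub
        )
        curve = km_estimate(ages, events)
        med, med_ci = km_median(curve)
        mfu = median_followup(ages, events)
        nfam = len(subfams)
        cols[label] = pd.Series(
            {
                "n_families": nfam,
                "mean_carriers_per_family": round(len(sub) / nfam, 1),
                "mean_diagnoses_per_family": round(ndiag / nfam, 1),
                "mean_generations_per_family": round(
                    sum(f.n_generations for f in subfams) / nfam, 1
                ),
                "range_generations_per_family": (
                    min(f.n_generations for f in subfams),
                    max(f.n_generations for f in subfams),
                ),
                "n_carriers": len(sub),
                "median_age_first_diagnosis": med,
                "median_age_ci95": med_ci,
                "median_followup": mfu,
                "pct_female": round(100.0 * np.mean([r.sex == "female" for r in sub]), 1),
            }
        )
    return pd.DataFrame(cols)
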