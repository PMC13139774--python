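"""Reading, validating and filtering COSMIC-style somatic mutation tables.

Input is a flat TSV/CSV with one row per observed somatic variant:
cohort (cancer-type label), sample_id, gene, chromosome, position, ref, alt.
Rows are parsed into :class:`MutationRecord` objects without any silent
drops; a separate explicit filtering pass removes non-SNVs, alternative
transcripts, non-canonical chromosomes etc. and accounts for every
exclusion in a :class:`FilterReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

BASES = frozenset("ACGT")

#: canonical human chromosome labels, in karyotype order
CANONICAL_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

DEFAULT_COLUMNS = {
    "cohort": "cohort",
    "sample_id": "sample_id",
    "gene": "gene",
    "chromosome": "chromosome",
    "position": "position",
    "ref": "ref",
    "alt": "alt",
}

#: fixed application order: structural validity before semantic filters
FILTER_RULES: tuple[str, ...] = (
    "malformed",
    "bad_chromosome",
    "not_snv",
    "ref_equals_alt",
    "alt_transcript",
    "non_coding",
)

#: substring marking alternative-transcript gene identifiers (e.g. TP53_ENST00000269305)
ALT_TRANSCRIPT_MARKER = "_ENST"


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant observation."""

    cohort: str
    sample_id: str
    gene: str
    chromosome: str
    position: int
    ref: str
    alt: str
    coding_flag: bool = True


@dataclass
class FilterReport:
    """Exact accounting of a filtering pass: n_input = n_retained + dropped."""

    n_input: int = 0
    n_retained: int = 0
    dropped_by_rule: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in FILTER_RULES}
    )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def check_conservation(self) -> bool:
        return self.n_input == self.n_retained + sum(self.dropped_by_rule.values())


def normalize_chromosome(label: object) -> str:
    """Normalize a chromosome label: strip a 'chr' prefix, uppercase X/Y/MT.

    Non-canonical results (``'23'``, ``'MT'``, alt contigs) are returned
    as-is and left for the ``bad_chromosome`` filter rule.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in {"X", "Y", "MT", "M"}:
        s = s.upper()
    return s


def read_mutation_table(
    path: str | Path,
    dialect: dict[str, str] | None = None,
) -> list[MutationRecord]:
    """Parse a mutation TSV/CSV into unfiltered records, one per data row.

    Parameters
    ----------
    path:
        File path; tab-separated if the suffix is ``.tsv``, comma otherwise.
    dialect:
        Optional mapping from the standard field names
        (cohort, sample_id, gene, chromosome, position, ref, alt,
        optionally coding_flag) to the column names in the file.

    Rows that cannot be parsed (e.g. a non-integer position) are kept with
    ``position=-1`` so the subsequent filter pass can charge them to the
    ``malformed`` rule — nothing is dropped silently here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.columns.size == 0:
        raise ValueError(f"{path}: empty header")
    missing = [c for k, c in cols.items() if k != "coding_flag" and c not in df.columns]
    if missing:
        raise KeyError(f"{path}: missing mapped columns {missing}")
    has_coding = "coding_flag" in cols and cols["coding_flag"] in df.columns

    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        try:
            pos = int(str(row[cols["position"]]).strip())
        except (ValueError, TypeError):
            pos = -1
        coding = True
        if has_coding:
            coding = str(row[cols["coding_flag"]]).strip().lower() in {
                "1", "true", "yes", "y", "coding",
            }
        records.append(
            MutationRecord(
                cohort=str(row[cols["cohort"]]).strip(),
                sample_id=str(row[cols["sample_id"]]).strip(),
                gene=str(row[cols["gene"]]).strip(),
                chromosome=normalize_chromosome(row[cols["chromosome"]]),
                position=pos,
                ref=str(row[cols["ref"]]).strip().upper(),
                alt=str(row[cols["alt"]]).strip().upper(),
                coding_flag=coding,
            )
        )
    return records


def _first_violated_rule(r: MutationRecord, rules: set[str], marker: str) -> str | None:
    if "malformed" in rules and (
        not r.cohort or not r.gene or not r.sample_id or r.position <= 0
    ):
        return "malformed"
    if "bad_chromosome" in rules and r.chromosome not in CANONICAL_CHROMOSOMES:
        return "bad_chromosome"
    if "not_snv" in rules and not (
        len(r.ref) == 1 and len(r.alt) == 1 and r.ref in BASES and r.alt in BASES
    ):
        return "not_snv"
    if "ref_equals_alt" in rules and r.ref == r.alt:
        return "ref_equals_alt"
    if "alt_transcript" in rules and marker in r.gene:
        return "alt_transcript"
    if "non_coding" in rules and not r.coding_flag:
        return "non_coding"
    return None


def filter_records(
    records: list[MutationRecord],
    rules: set[str] | None = None,
    transcript_marker: str = ALT_TRANSCRIPT_MARKER,
) -> tuple[list[MutationRecord], FilterReport]:
    """Apply the curation rules in fixed order; never raises on bad records.

    Each record is charged to the *first* rule it violates, so the report is
    deterministic and the counts are conservative:
    n_input = n_retained + sum(dropped).
    """
    if rules is None:
        rules = set(FILTER_RULES)
    unknown = rules - set(FILTER_RULES)
    if unknown:
        raise ValueError(f"unknown filter rules: {sorted(unknown)}")
    report = FilterReport(n_input=len(records))
    retained: list[MutationRecord] = []
    for r in records:
        rule = _first_violated_rule(r, rules, transcript_marker)
        if rule is None:
            retained.append(r)
        else:
            report.dropped_by_rule[rule] += 1
    report.n_retained = len(retained)
    return retained, report


def dedup_records(records: list[MutationRecord]) -> list[MutationRecord]:
    """Collapse duplicate (sample, variant) rows, keeping first occurrence."""
    seen: set[tuple] = set()
    out = []
    for r in records:
        key = (r.cohort, r.sample_id, r.gene, r.chromosome, r.position, r.ref, r.alt)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def records_to_frame(records: list[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [asdict(r) for r in records],
        columns=list(DEFAULT_COLUMNS) + ["coding_flag"],
    )


def write_mutation_table(records: list[MutationRecord], path: str | Path) -> None:
    """Write records back out as TSV/CSV in the standard column layout."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = records_to_frame(records).drop(columns=["coding_flag"])
    df.to_csv(path, sep=sep, index=False)
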