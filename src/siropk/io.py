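"""Dataset CSV reading/writing in a NONMEM-style longitudinal layout.

Schema (canonical column order; header exact; UTF-8):

    ID, TIME, EVID, AMT, DV, WT, SEX, AGE, POS, CEF, OME, SMZ,
    ALB, ALT, AST, CREA, UREA, TP, TBA, DBIL, TBIL, HCT, HGB, MCH, MCHC

``ID`` integer; ``TIME`` hours since first dose; ``EVID`` 1 for dose rows and
0 for observation rows; ``AMT`` micrograms on dose rows only; ``DV`` ng/ml on
observation rows only.  Covariates are constant within a subject and repeated
on every row.  Missing numeric cells use the explicit "." token (NONMEM
convention), never the empty string.  Rows are sorted by (ID, TIME); within a
subject a dose and an observation may share a time (the observation is the
pre-dose trough).  Columns after WT are optional but must appear in canonical
order.  Floats are written with the shortest representation that round-trips
exactly, so write -> read -> write is byte-stable.
"""

from __future__ import annotations

import csv

from .data import COVARIATE_ORDER, Dataset, Subject
from .errors import SchemaError

REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "DV", "WT")
CANONICAL_COLUMNS = REQUIRED_COLUMNS + COVARIATE_ORDER
MISSING = "."


def _format(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, int):
        return str(value)
    return repr(float(value))


def _parse(token: str, column: str, row_num: int):
    token = token.strip()
    if token == MISSING or token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise SchemaError(f"row {row_num}: cannot parse {column}={token!r}") from None


def write_dataset(dataset: Dataset, path) -> None:
    """Write the dataset in canonical column order with deterministic bytes."""
    dataset.validate()
    present = [c for c in COVARIATE_ORDER
               if any(c in s.covariates for s in dataset.subjects)]
    columns = list(REQUIRED_COLUMNS) + present
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for s in sorted(dataset.subjects, key=lambda s: s.id):
            events = sorted(
                [(t, 1, amt, None) for t, amt in s.doses]
                + [(t, 0, None, dv) for t, dv in s.observations],
                key=lambda e: (e[0], -e[1]),  # dose row first at shared times
            )
            for t, evid, amt, dv in events:
                row = [str(int(s.id)), _format(t), str(evid), _format(amt), _format(dv),
                       _format(s.weight)]
                row += [_format(s.covariates.get(c)) for c in present]
                writer.writerow(row)


def read_dataset(path) -> Dataset:
    """Read and validate a dataset CSV written in the documented schema."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file") from None
        unknown = [c for c in header if c not in CANONICAL_COLUMNS]
        if unknown:
            raise SchemaError(f"unknown columns: {unknown}")
        missing_req = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing_req:
            raise SchemaError(f"missing required columns: {missing_req}")
        canonical_present = [c for c in CANONICAL_COLUMNS if c in header]
        if header != canonical_present:
            raise SchemaError(
                f"columns out of canonical order: got {header}, expected {canonical_present}"
            )
        cov_cols = [c for c in header if c in COVARIATE_ORDER]

        subjects: dict[int, Subject] = {}
        order: list[int] = []
        seen_keys = set()
        last_key = None
        for row_num, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise SchemaError(f"row {row_num}: expected {len(header)} cells, got {len(row)}")
            rec = dict(zip(header, row))
            try:
                sid = int(rec["ID"])
                evid = int(rec["EVID"])
            except ValueError:
                raise SchemaError(f"row {row_num}: ID and EVID must be integers") from None
            if evid not in (0, 1):
                raise SchemaError(f"row {row_num}: EVID must be 0 or 1")
            time = _parse(rec["TIME"], "TIME", row_num)
            amt = _parse(rec["AMT"], "AMT", row_num)
            dv = _parse(rec["DV"], "DV", row_num)
            wt = _parse(rec["WT"], "WT", row_num)
            if time is None or wt is None:
                raise SchemaError(f"row {row_num}: TIME and WT are required")

            key = (sid, time, evid)
            if key in seen_keys:
                raise SchemaError(f"row {row_num}: duplicate (ID, TIME, EVID) {key}")
            seen_keys.add(key)
            sort_key = (sid, time)
            if last_key is not None and sort_key < last_key:
                raise SchemaError(f"row {row_num}: rows not sorted by (ID, TIME)")
            last_key = sort_key

            if evid == 1:
                if dv is not None:
                    raise SchemaError(f"row {row_num}: dose row must have empty DV")
                if amt is None or amt < 0:
                    raise SchemaError(f"row {row_num}: dose row needs AMT >= 0")
            else:
                if amt is not None:
                    raise SchemaError(f"row {row_num}: observation row must have empty AMT")
                if dv is None or dv <= 0:
                    raise SchemaError(f"row {row_num}: observation row needs DV > 0")

            if sid not in subjects:
                covs = {}
                for c in cov_cols:
                    v = _parse(rec[c], c, row_num)
                    if v is not None:
                        covs[c] = v
                subjects[sid] = Subject(id=sid, weight=wt, covariates=covs)
                order.append(sid)
            if evid == 1:
                subjects[sid].doses.append((time, amt))
            else:
                subjects[sid].observations.append((time, dv))

    dataset = Dataset([subjects[sid] for sid in order])
    dataset.validate()
    return dataset
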