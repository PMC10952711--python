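"""Reading and writing the CASP QA QMODE2 submission format.

A QMODE2 file carries, per model, a global fold score (SCORE), an interface
score (QSCORE) and one confidence value per residue estimating how likely
the residue is to belong to the interface.  Scores are printed to three
decimals, residue values wrapped twenty per line on continuation lines, and
unassessed residues marked ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .consensus import QualityEstimate

__all__ = [
    "Qmode2Record",
    "Qmode2FormatError",
    "write_qmode2",
    "parse_qmode2",
]

VALUES_PER_LINE = 20


class Qmode2FormatError(ValueError):
    """Malformed QMODE2 content; the message names the offending line."""


@dataclass
class Qmode2Record:
    """One model's scores as they appear in a QMODE2 file."""

    target_id: str
    model_name: str
    score: float
    qscore: float
    residue_scores: list[float | None]  # None = not assessed ("X")


def _fmt(v: float) -> str:
    return f"{v:.3f}"


def _check_range(value: float, what: str, model: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{what} {value} of model {model} outside [0,1]; refusing to write")


def write_qmode2(estimates: list[QualityEstimate], target_id: str, author: str,
                 method_text: str, path: str | Path,
                 qmode: int = 2) -> None:
    """Write quality estimates as a QMODE2 (or, with ``qmode=1``, QMODE1) file.

    QMODE1 output simply truncates the per-residue part of each record.
    Unscored estimates are skipped; residue values of ``None`` are written as
    the not-assessed marker ``X``.
    """
    if qmode not in (1, 2):
        raise ValueError("qmode must be 1 or 2")
    rows = [e for e in estimates if not e.unscored]
    if not rows:
        raise ValueError("no scored estimates to write")
    lines = [
        "PFRMAT QA",
        f"TARGET {target_id}",
        f"AUTHOR {author}",
        f"METHOD {method_text}",
        "MODEL 1",
        f"QMODE {qmode}",
    ]
    for est in rows:
        score = est.score if est.score is not None else 0.0
        qscore = est.qscore if est.qscore is not None else 0.0
        _check_range(score, "SCORE", est.model_id)
        _check_range(qscore, "QSCORE", est.model_id)
        head = f"{est.model_id} {_fmt(score)} {_fmt(qscore)}"
        if qmode == 1:
            lines.append(head)
            continue
        tokens: list[str] = []
        for v in est.residue_conf or []:
            if v is None:
                tokens.append("X")
            else:
                _check_range(v, "residue score", est.model_id)
                tokens.append(_fmt(v))
        first, rest = tokens[:VALUES_PER_LINE], tokens[VALUES_PER_LINE:]
        lines.append((head + " " + " ".join(first)).rstrip())
        for k in range(0, len(rest), VALUES_PER_LINE):
            lines.append(" ".join(rest[k:k + VALUES_PER_LINE]))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_value(token: str, lineno: int) -> float | None:
    if token == "X":
        return None
    try:
        v = float(token)
    except ValueError:
        raise Qmode2FormatError(f"line {lineno}: non-numeric score {token!r}") from None
    if not 0.0 <= v <= 1.0:
        raise Qmode2FormatError(f"line {lineno}: score {v} outside [0,1]")
    return v


def parse_qmode2(path: str | Path,
                 expected_residues: int | None = None) -> list[Qmode2Record]:
    """Parse a QMODE2 file back into records (inverse of :func:`write_qmode2`).

    Tolerates extra whitespace and preserves ``X`` markers.  With
    ``expected_residues`` set, records carrying a different number of residue
    values raise a truncation error.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    target = ""
    qmode = None
    records: list[Qmode2Record] = []
    current: Qmode2Record | None = None
    in_body = False
    ended = False

    def finish(rec: Qmode2Record, lineno: int) -> None:
        if expected_residues is not None and qmode == 2 \
                and len(rec.residue_scores) != expected_residues:
            raise Qmode2FormatError(
                f"line {lineno}: model {rec.model_name} has {len(rec.residue_scores)} "
                f"residue scores, expected {expected_residues} (truncated record?)"
            )
        records.append(rec)

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        key = tokens[0]
        if key == "PFRMAT":
            continue
        if key == "TARGET":
            target = tokens[1] if len(tokens) > 1 else ""
            continue
        if key in ("AUTHOR", "METHOD", "MODEL", "REMARK"):
            continue
        if key == "QMODE":
            try:
                qmode = int(tokens[1])
            except (IndexError, ValueError):
                raise Qmode2FormatError(f"line {lineno}: malformed QMODE line") from None
            in_body = True
            continue
        if key == "END":
            ended = True
            break
        if not in_body:
            raise Qmode2FormatError(f"line {lineno}: record before QMODE declaration")
        # continuation line: every token parses as a residue value
        is_continuation = current is not None and all(
            t == "X" or _is_float(t) for t in tokens
        )
        if is_continuation:
            current.residue_scores.extend(_parse_value(t, lineno) for t in tokens)
            continue
        if current is not None:
            finish(current, lineno)
        if len(tokens) < 3:
            raise Qmode2FormatError(f"line {lineno}: record needs name, SCORE and QSCORE")
        score = _parse_value(tokens[1], lineno)
        qscore = _parse_value(tokens[2], lineno)
        if score is None or qscore is None:
            raise Qmode2FormatError(f"line {lineno}: SCORE/QSCORE may not be 'X'")
        current = Qmode2Record(
            target_id=target,
            model_name=tokens[0],
            score=score,
            qscore=qscore,
            residue_scores=[_parse_value(t, lineno) for t in tokens[3:]],
        )
    if qmode is None:
        raise Qmode2FormatError("missing QMODE line")
    if current is not None:
        finish(current, len(lines))
    if not ended:
        raise Qmode2FormatError("missing END line (truncated file)")
    if not records:
        raise Qmode2FormatError("no model records found")
    return records


def _is_float(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True
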