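"""Selection-matrix CSV dialect and writers.

Long format with header ``rater,case,action_id,selected`` and one row
per (rater, case, action); ``selected`` is 0 or 1.  A (rater, case)
block that is absent entirely means the rater did not answer the case;
a block of all-zero rows means they answered and selected nothing.
``write_selection_csv(read_selection_csv(path))`` is byte-identical
for canonical files (rows sorted by rater, case, action).
"""

from __future__ import annotations

import csv
from pathlib import Path

from .errors import ValidationError
from .stats import DEFAULT_MAX_SELECT, DEFAULT_N_ACTIONS, SelectionMatrix

HEADER = ["rater", "case", "action_id", "selected"]


def read_selection_csv(
    path: str | Path,
    n_actions: int = DEFAULT_N_ACTIONS,
    max_select: int = DEFAULT_MAX_SELECT,
) -> SelectionMatrix:
    """Read and validate a selection matrix.

    Raises :class:`ValidationError` for a malformed header or row, a
    ``selected`` value outside {0, 1}, duplicate (rater, case, action)
    rows, or a block exceeding ``max_select`` selections.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        if [h.strip() for h in header] != HEADER:
            raise ValidationError(
                f"{path}: header must be {','.join(HEADER)!r}, got {header}"
            )
        raters: list[str] = []
        cases: list[str] = []
        seen: set[tuple[str, str, int]] = set()
        selections: dict[tuple[str, str], set[int]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            rater, case, action_s, selected_s = (c.strip() for c in row)
            try:
                action = int(action_s)
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: bad action_id {action_s!r}") from None
            if selected_s not in ("0", "1"):
                raise ValidationError(
                    f"{path}:{lineno}: selected must be 0 or 1, got {selected_s!r}"
                )
            key = (rater, case, action)
            if key in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate row for rater {rater}, "
                    f"case {case}, action {action}"
                )
            seen.add(key)
            if rater not in raters:
                raters.append(rater)
            if case not in cases:
                cases.append(case)
            block = selections.setdefault((rater, case), set())
            if selected_s == "1":
                block.add(action)
    if not seen:
        raise ValidationError(f"{path}: no data rows")
    for (rater, case), sel in selections.items():
        if len(sel) > max_select:
            raise ValidationError(
                f"{path}: rater {rater}, case {case} selected {len(sel)} actions, "
                f"limit is {max_select}"
            )
    return SelectionMatrix(
        raters=tuple(raters),
        cases=tuple(cases),
        n_actions=n_actions,
        max_select=max_select,
        selections={k: frozenset(v) for k, v in selections.items()},
    )


def write_selection_csv(matrix: SelectionMatrix, path: str | Path) -> None:
    """Write a matrix in the canonical dialect (sorted, LF line endings)."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(HEADER)
        for rater in matrix.raters:
            for case in matrix.cases:
                if not matrix.answered(rater, case):
                    continue
                sel = matrix.selected(rater, case)
                for action in range(1, matrix.n_actions + 1):
                    writer.writerow([rater, case, action, int(action in sel)])
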