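"""Likelihood-ratio tests over harvested results, and the table session.

Two nested codon models are compared with the statistic
``2ΔlnL = 2 (lnL_alt − lnL_null)`` referred to a chi-square distribution
with ``df = np_alt − np_null`` degrees of freedom; the alternative is
accepted (H1) when the upper-tail probability falls below the chosen alpha.
A negative 2ΔlnL (the alternative fitting *worse*, possible when codeml is
trapped in a local optimum or the rows were swapped) is clamped to 0, so
p = 1 and the null is retained, with a swap-suspected warning.

For the boundary-constrained comparisons (M8a vs M8, TrC vs TrU — testing
ω = 1 on the edge of the parameter space) the default is the plain
chi-square; ``boundary_mixture=True`` applies the 50:50 mixture of χ²₀ and
χ²_df instead, which halves the p-value.

The table session mirrors the interactive results-manipulation workflow:
a User Table loaded from CSV, a Final Table assembled from selected rows,
positional column aliases C1..Cn, hide/sort/select commands, and ``plrt``,
which consumes consecutive (null above alternative) row pairs and appends
exactly five columns — comparison, deltaLnL, df, p-value, conclusion —
filled only on the alternative rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .errors import ValidationError
from .templates import comparisons_registry

#: the five columns plrt appends, in fixed order
LRT_COLUMNS = ["comparison", "deltaLnL", "df", "p-value", "conclusion"]

_PAIRS = {(c.null_name, c.alt_name): c for c in comparisons_registry()}

#: canonical degrees of freedom per comparison, used to cross-validate df
CANONICAL_DF = {"M0vM3": 4, "M1avM2a": 2, "M7vM8": 2, "M8avM8": 1,
                "M0vTrU": 1, "TrCvTrU": 1, "MA1vMA": 1, "M2a_relvCmC": 1}


@dataclass
class LrtResult:
    label: str
    delta: float
    df: int
    p_value: float
    conclusion: str
    alpha: float
    warning: str | None = None


def chi2_upper_tail(x: float, df: int) -> float:
    """P(X >= x) for X ~ chi-square(df)."""
    return float(stats.chi2.sf(x, df))


def compute_lrt(null, alt, alpha: float = 0.05, force: bool = False,
                boundary_mixture: bool = False) -> LrtResult:
    """LRT between a null and an alternative ResultRecord.

    The (null.model, alt.model) pair must appear in the comparisons registry
    unless *force*; np_alt must exceed np_null (nested as ordered).
    """
    key = (null.model, alt.model)
    comp = _PAIRS.get(key)
    if comp is None and not force:
        raise ValidationError(
            f"{null.model} vs {alt.model} is not a registered nested pair")
    if alt.np <= null.np:
        raise ValidationError(
            f"np_alt ({alt.np}) must exceed np_null ({null.np}): "
            "models are not nested as ordered")
    label = comp.label if comp else f"{null.model}v{alt.model}"
    df = alt.np - null.np
    delta = 2.0 * (alt.lnL - null.lnL)
    warning = None
    if comp and CANONICAL_DF.get(label) not in (None, df):
        warning = (f"df {df} from np differs from the canonical "
                   f"{CANONICAL_DF[label]} for {label}")
    if delta < -1e-6:
        warning = ((warning + "; ") if warning else "") + \
            "negative 2dlnL: null fits better — swapped rows suspected"
    x = max(delta, 0.0)
    p = chi2_upper_tail(x, df)
    if boundary_mixture:
        p = 0.5 * p if x > 0 else 1.0
    conclusion = "H1" if (p < alpha and delta > 0) else "H0"
    return LrtResult(label=label, delta=delta, df=df, p_value=p,
                     conclusion=conclusion, alpha=alpha, warning=warning)


@dataclass
class _Rec:
    model: str
    lnL: float
    np: int


@dataclass
class TableSession:
    """User/Final table pair with a command-driven view state."""

    user: pd.DataFrame
    final: pd.DataFrame
    active: str = "U"                       # U | F
    hidden: set = field(default_factory=set)      # 1-based column positions
    selected: list = field(default_factory=list)  # 1-based row positions
    visible_rows: int = 20
    full_headers: bool = False
    messages: list = field(default_factory=list)

    @classmethod
    def from_csv(cls, path) -> "TableSession":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TableSession":
        return cls(user=df.reset_index(drop=True),
                   final=df.iloc[0:0].copy())

    @property
    def table(self) -> pd.DataFrame:
        return self.user if self.active == "U" else self.final

    @table.setter
    def table(self, df):
        if self.active == "U":
            self.user = df
        else:
            self.final = df

    def aliases(self) -> dict:
        return {f"C{i}": col for i, col in enumerate(self.table.columns, 1)}


def plrt(session: TableSession, alpha: float,
         boundary_mixture: bool = False) -> TableSession:
    """Run LRTs over the selected consecutive (null, alt) row pairs.

    Operates on the Final Table.  Appends (or replaces — idempotent) the
    five LRT columns; results land on alternative-model rows only, null
    rows stay blank.  Pairs that fail the nesting preconditions are flagged
    in ``session.messages`` and skipped; the rest are processed.
    """
    df = session.final
    sel = sorted(session.selected)
    if not sel:
        session.messages.append("plrt: no rows selected; table unchanged")
        return session
    if len(sel) % 2:
        session.messages.append(
            f"plrt: odd number of selected rows ({len(sel)}); last one ignored")
        sel = sel[:-1]
    for col in LRT_COLUMNS:
        df[col] = ""
    for null_pos, alt_pos in zip(sel[0::2], sel[1::2]):
        null_row = df.iloc[null_pos - 1]
        alt_row = df.iloc[alt_pos - 1]
        try:
            res = compute_lrt(
                _Rec(null_row["model"], float(null_row["lnL"]), int(null_row["np"])),
                _Rec(alt_row["model"], float(alt_row["lnL"]), int(alt_row["np"])),
                alpha=alpha, boundary_mixture=boundary_mixture,
            )
        except (ValidationError, KeyError, ValueError) as e:
            session.messages.append(f"plrt: rows {null_pos},{alt_pos}: {e}")
            continue
        if res.warning:
            session.messages.append(f"plrt: rows {null_pos},{alt_pos}: {res.warning}")
        i = df.index[alt_pos - 1]
        df.loc[i, "comparison"] = res.label
        df.loc[i, "deltaLnL"] = f"{res.delta:.6f}"
        df.loc[i, "df"] = str(res.df)
        df.loc[i, "p-value"] = f"{res.p_value:.6g}"
        df.loc[i, "conclusion"] = res.conclusion
    session.final = df
    return session


def _parse_col_range(token: str, ncols: int) -> list:
    m = re.fullmatch(r"C(\d+)(?:-(\d+))?", token)
    if not m:
        raise ValidationError(f"bad column reference {token!r}")
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) else lo
    if not (1 <= lo <= hi <= ncols):
        raise ValidationError(f"column range {token!r} outside 1..{ncols}")
    return list(range(lo, hi + 1))


def _parse_rows(token: str, nrows: int) -> list:
    if token == "all":
        return list(range(1, nrows + 1))
    if token == "none":
        return []
    out = []
    for part in token.split(","):
        m = re.fullmatch(r"(\d+)(?:-(\d+))?", part)
        if not m:
            raise ValidationError(f"bad row reference {part!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if not (1 <= lo <= hi <= nrows):
            raise ValidationError(f"row range {part!r} outside 1..{nrows}")
        out.extend(range(lo, hi + 1))
    return out


HELP_TEXT = """commands:
  u | f              switch to the User / Final table
  select <rows|all|none>   select rows, e.g. select 1-4,7
  copy               append selected User rows to the Final table
  sort C<n> [d]      sort active table by column (d = descending)
  hide C<a>[-<b>]    hide columns;  unhide C<a>[-<b>] | unhide all
  fh                 toggle full headers vs C<n> aliases
  rows <n>           set number of visible rows
  plrt <alpha>       run LRTs over selected (null, alt) row pairs
  save <path>        write the active table to CSV
  ?                  this help
"""


def apply_command(session: TableSession, command: str) -> TableSession:
    """Apply one textual command to the session; unknown input is a no-op
    with a message.  View commands never mutate the underlying data."""
    cmd = command.strip()
    parts = cmd.split()
    if not parts:
        return session
    op, args = parts[0], parts[1:]
    try:
        if op == "?":
            session.messages.append(HELP_TEXT)
        elif op in ("u", "f"):
            session.active = op.upper()
            session.selected = []
        elif op == "select" and len(args) == 1:
            session.selected = _parse_rows(args[0], len(session.table))
        elif op == "copy":
            if session.active != "U":
                raise ValidationError("copy takes selected rows from the User table")
            rows = session.user.iloc[[r - 1 for r in session.selected]]
            session.final = pd.concat([session.final, rows], ignore_index=True)
        elif op == "sort" and args:
            cols = _parse_col_range(args[0], len(session.table.columns))
            name = session.table.columns[cols[0] - 1]
            ascending = not (len(args) > 1 and args[1] == "d")
            session.table = (session.table
                             .sort_values(name, ascending=ascending, kind="stable")
                             .reset_index(drop=True))
        elif op == "hide" and len(args) == 1:
            session.hidden |= set(_parse_col_range(args[0], len(session.table.columns)))
        elif op == "unhide" and len(args) == 1:
            if args[0] == "all":
                session.hidden = set()
            else:
                session.hidden -= set(_parse_col_range(args[0],
                                                       len(session.table.columns)))
        elif op == "fh":
            session.full_headers = not session.full_headers
        elif op == "rows" and len(args) == 1:
            session.visible_rows = max(1, int(args[0]))
        elif op == "plrt" and len(args) >= 1:
            plrt(session, float(args[0]))
        elif op == "save" and len(args) == 1:
            session.table.to_csv(args[0], index=False)
            session.messages.append(f"saved {len(session.table)} rows to {args[0]}")
        else:
            session.messages.append(f"unknown command {cmd!r} (try ?)")
    except (ValidationError, ValueError) as e:
        session.messages.append(f"{op}: {e}")
    return session


def render_table(session: TableSession) -> str:
    """Plain-text view of the active table under the session's view state."""
    df = session.table
    visible = [i for i in range(1, len(df.columns) + 1) if i not in session.hidden]
    headers = [df.columns[i - 1] if session.full_headers else f"C{i}"
               for i in visible]
    lines = ["  ".join(headers)]
    for _, row in df.head(session.visible_rows).iterrows():
        lines.append("  ".join(str(row.iloc[i - 1]) for i in visible))
    c = (f"[{session.active}] rows {len(df)}  cols {len(df.columns)}  "
         f"selected {len(session.selected)}  hidden {len(session.hidden)}")
    lines.append(c)
    return "\n".join(lines)


def auto_pair_lrt(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Non-interactive convenience: pair rows per the comparisons registry.

    Groups the harvested table by dataset and grid starting point, emits a
    (null, alternative) row pair for every registry comparison whose two
    models are both present in the group, and runs ``plrt`` over all pairs.
    Returns the Final Table with the five LRT columns.
    """
    df = table.reset_index(drop=True)
    pairs = []
    group_cols = ["gene", "tree_ref", "kappa0", "omega0"]
    for _, group in df.groupby(group_cols, sort=True):
        by_model = {}
        for idx, row in group.iterrows():
            by_model.setdefault(row["model"], idx)
        for comp in comparisons_registry():
            if comp.null_name in by_model and comp.alt_name in by_model:
                pairs.append((by_model[comp.null_name], by_model[comp.alt_name]))
    if not pairs:
        out = df.copy()
        for col in LRT_COLUMNS:
            out[col] = ""
        return out
    order = [i for pair in pairs for i in pair]
    final = df.iloc[order].reset_index(drop=True)
    session = TableSession(user=df, final=final,
                           selected=list(range(1, len(final) + 1)))
    plrt(session, alpha)
    return session.final
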