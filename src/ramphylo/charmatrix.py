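"""Species x ortholog binary presence/absence matrices.

The matrix cell for (species, ortholog) is 1 when the species' copy of the
ortholog carries a ramp sequence, 0 when it does not, and missing ('?') when
the species has no annotation for the ortholog. Internally a pandas
DataFrame (rows = species, columns = orthologs, float values with NaN for
missing) backs the matrix.

Filtering follows the two-pass scheme used for the vertebrate dataset:
pass 1 keeps orthologs whose ramp is present in at least 5% AND absent in at
least 5% of the species annotated for it; pass 2 then drops species
annotated for fewer than 5% of the surviving orthologs. Characters entering
homoplasy scoring must additionally be present in >= 2 and absent in >= 2
species (autapomorphies carry no phylogenetic information).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConflictError, EmptyInputError, EmptyResultError

logger = logging.getLogger(__name__)

__all__ = [
    "CharacterMatrix",
    "FilterConfig",
    "FilterReport",
    "build_matrix",
    "filter_matrix",
    "informative_characters",
    "write_matrix",
    "read_matrix",
]


class CharacterMatrix:
    """Binary character matrix with explicit missing entries."""

    def __init__(self, dataframe):
        df = pd.DataFrame(dataframe).astype(float)
        if df.index.duplicated().any():
            raise ValueError("duplicate species names")
        if df.columns.duplicated().any():
            raise ValueError("duplicate ortholog ids")
        vals = df.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("cells must be 0, 1 or missing")
        self._df = df

    # -- accessors ---------------------------------------------------------
    @property
    def species(self):
        return list(self._df.index)

    @property
    def orthologs(self):
        return list(self._df.columns)

    @property
    def shape(self):
        return self._df.shape

    def state(self, species, ortholog):
        """0, 1 or None (missing)."""
        v = self._df.at[species, ortholog]
        return None if pd.isna(v) else int(v)

    def column(self, ortholog):
        """Mapping species -> 0/1/None for one character."""
        col = self._df[ortholog]
        return {sp: (None if pd.isna(v) else int(v)) for sp, v in col.items()}

    def to_dataframe(self):
        return self._df.copy()

    def restrict_species(self, species):
        return CharacterMatrix(self._df.loc[list(species)])

    def equals(self, other):
        a, b = self._df, other._df
        return (
            list(a.index) == list(b.index)
            and list(a.columns) == list(b.columns)
            and ((a.values == b.values) | (np.isnan(a.values) & np.isnan(b.values))).all()
        )

    def __repr__(self):
        ns, no = self._df.shape
        return f"<CharacterMatrix {ns} species x {no} orthologs>"


@dataclass
class FilterConfig:
    """Thresholds for matrix filtering and character informativeness."""

    min_presence_fraction: float = 0.05
    min_absence_fraction: float = 0.05
    min_species_coverage: float = 0.05
    min_informative_count: int = 2

    def __post_init__(self):
        for f in (self.min_presence_fraction, self.min_absence_fraction,
                  self.min_species_coverage):
            if not 0.0 <= f <= 1.0:
                raise ValueError("filter fractions must lie in [0, 1]")
        if self.min_informative_count < 2:
            raise ValueError("min_informative_count must be >= 2")


@dataclass
class FilterReport:
    """What each filtering pass removed, plus missing-data summaries."""

    dropped_orthologs: list = field(default_factory=list)  # (id, reason)
    dropped_species: list = field(default_factory=list)    # (name, reason)
    missing_percent: dict = field(default_factory=dict)    # species -> %
    missing_mean: float = float("nan")
    missing_std: float = float("nan")


def build_matrix(calls, ortholog_universe=None, species_universe=None):
    """Assemble a CharacterMatrix from ramp calls.

    A cell is 1/0 per the call's ``has_ramp``; (species, ortholog) pairs with
    no call are missing. Conflicting duplicate calls raise
    :class:`ConflictError` — silent voting could mask upstream bugs.
    """
    calls = list(calls)
    if not calls:
        raise EmptyInputError("no ramp calls supplied")
    cells = {}
    for c in calls:
        key = (c.species, c.ortholog_id)
        val = 1.0 if c.has_ramp else 0.0
        if key in cells and cells[key] != val:
            raise ConflictError(f"conflicting calls for species={key[0]!r} ortholog={key[1]!r}")
        cells[key] = val
    species = sorted({s for s, _ in cells})
    orthologs = sorted({o for _, o in cells})
    if species_universe is not None:
        species = sorted(set(species) | set(species_universe))
    if ortholog_universe is not None:
        orthologs = sorted(set(orthologs) | set(ortholog_universe))
    df = pd.DataFrame(np.nan, index=species, columns=orthologs, dtype=float)
    for (s, o), v in cells.items():
        df.at[s, o] = v
    return CharacterMatrix(df)


def filter_matrix(matrix, config=None):
    """Two-pass filter; returns (filtered matrix, report).

    Pass 1 (orthologs): presence fraction >= ``min_presence_fraction`` AND
    absence fraction >= ``min_absence_fraction``, fractions taken over the
    species annotated (non-missing) for that ortholog, boundary inclusive.
    Pass 2 (species): drop species annotated for less than
    ``min_species_coverage`` of the surviving orthologs.
    """
    if config is None:
        config = FilterConfig()
    df = matrix.to_dataframe()
    report = FilterReport()

    n_annot = df.notna().sum(axis=0)
    n_pres = (df == 1.0).sum(axis=0)
    n_abs = (df == 0.0).sum(axis=0)
    keep_orth = []
    for o in df.columns:
        if n_annot[o] == 0:
            report.dropped_orthologs.append((o, "no annotated species"))
            continue
        pf = n_pres[o] / n_annot[o]
        af = n_abs[o] / n_annot[o]
        if pf < config.min_presence_fraction:
            report.dropped_orthologs.append((o, f"presence fraction {pf:.3f} < {config.min_presence_fraction}"))
        elif af < config.min_absence_fraction:
            report.dropped_orthologs.append((o, f"absence fraction {af:.3f} < {config.min_absence_fraction}"))
        else:
            keep_orth.append(o)
    df1 = df[keep_orth]

    keep_sp = []
    if keep_orth:
        cov = df1.notna().sum(axis=1) / len(keep_orth)
        for s in df1.index:
            if cov[s] < config.min_species_coverage:
                report.dropped_species.append((s, f"coverage {cov[s]:.3f} < {config.min_species_coverage}"))
            else:
                keep_sp.append(s)
    df2 = df1.loc[keep_sp]

    if df2.empty:
        raise EmptyResultError("filtering removed all species or orthologs", report)

    miss = df2.isna().mean(axis=1) * 100.0
    report.missing_percent = {s: float(m) for s, m in miss.items()}
    report.missing_mean = float(miss.mean())
    report.missing_std = float(miss.std(ddof=1)) if len(miss) > 1 else 0.0
    logger.info(
        "filter: kept %d/%d orthologs, %d/%d species; missing %.2f%% +/- %.2f%%",
        len(keep_orth), df.shape[1], len(keep_sp), df.shape[0],
        report.missing_mean, report.missing_std,
    )
    return CharacterMatrix(df2), report


def informative_characters(matrix, config=None):
    """Orthologs present in >= k and absent in >= k species (default k=2)."""
    if config is None:
        config = FilterConfig()
    df = matrix.to_dataframe()
    k = config.min_informative_count
    n1 = (df == 1.0).sum(axis=0)
    n0 = (df == 0.0).sum(axis=0)
    return [o for o in df.columns if n1[o] >= k and n0[o] >= k]


# ---------------------------------------------------------------------------
# serialization

_RESERVED = re.compile(r"[\s();:,\[\]'\"=]")


def _sanitize_names(names):
    mapping = {}
    seen = set()
    for name in names:
        clean = _RESERVED.sub("_", name)
        base = clean
        i = 1
        while clean in seen:
            i += 1
            clean = f"{base}.{i}"
        seen.add(clean)
        if clean != name:
            logger.info("sanitized taxon name %r -> %r", name, clean)
        mapping[name] = clean
    return mapping


def _row_string(df, sp):
    out = []
    for v in df.loc[sp]:
        out.append("?" if pd.isna(v) else str(int(v)))
    return "".join(out)


def write_matrix(matrix, fmt):
    """Serialize to 'tsv' (native), 'nexus', 'tnt' (xread) or 'phylip' text.

    Missing cells render as '?'. Species names containing format-reserved
    characters are sanitized with a logged mapping. The companion
    :func:`read_matrix` round-trips every format.
    """
    df = matrix.to_dataframe()
    ns, nc = df.shape
    if fmt == "tsv":
        buf = io.StringIO()
        out = df.copy()
        out.index.name = "species"
        out.to_csv(buf, sep="\t", float_format="%.0f", na_rep="?")
        return buf.getvalue()

    names = _sanitize_names(df.index)
    pad = max(len(n) for n in names.values()) + 2
    if fmt == "nexus":
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"DIMENSIONS NTAX={ns} NCHAR={nc};",
            'FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="01";',
            "CHARLABELS " + " ".join(df.columns) + ";",
            "MATRIX",
        ]
        for sp in df.index:
            lines.append(f"{names[sp]:<{pad}}{_row_string(df, sp)}")
        lines += [";", "END;"]
        return "\n".join(lines) + "\n"
    if fmt == "tnt":
        lines = ["xread", f"{nc} {ns}"]
        for sp in df.index:
            lines.append(f"{names[sp]:<{pad}}{_row_string(df, sp)}")
        lines.append(";")
        return "\n".join(lines) + "\n"
    if fmt == "phylip":
        lines = [f"{ns} {nc}"]
        for sp in df.index:
            lines.append(f"{names[sp]:<{pad}}{_row_string(df, sp)}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown matrix format {fmt!r}")


def _rows_to_matrix(rows, orthologs=None):
    species = [r[0] for r in rows]
    nc = len(rows[0][1])
    if orthologs is None:
        width = len(str(nc))
        orthologs = [f"char{str(i + 1).zfill(width)}" for i in range(nc)]
    data = []
    for _, states in rows:
        data.append([np.nan if ch == "?" else float(ch) for ch in states])
    return CharacterMatrix(pd.DataFrame(data, index=species, columns=orthologs))


def read_matrix(text, fmt):
    """Parse matrix text produced by :func:`write_matrix`."""
    if fmt == "tsv":
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
        df = df.apply(lambda col: col.map(lambda v: np.nan if v == "?" else float(v)))
        return CharacterMatrix(df)
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if fmt == "nexus":
        orthologs = None
        rows = []
        in_matrix = False
        for ln in lines:
            up = ln.upper()
            if up.startswith("CHARLABELS"):
                orthologs = ln.rstrip(";").split()[1:]
            elif up == "MATRIX":
                in_matrix = True
            elif in_matrix:
                if ln == ";" or up.startswith("END"):
                    in_matrix = False
                    continue
                name, states = ln.split(None, 1)
                rows.append((name, states.rstrip(";")))
        return _rows_to_matrix(rows, orthologs)
    if fmt == "tnt":
        if lines[0].lower() != "xread":
            raise ValueError("not a TNT xread block")
        nc, ns = (int(x) for x in lines[1].split())
        rows = []
        for ln in lines[2:]:
            if ln == ";":
                break
            name, states = ln.split(None, 1)
            rows.append((name, states))
        if len(rows) != ns or any(len(st) != nc for _, st in rows):
            raise ValueError("TNT dimensions do not match matrix body")
        return _rows_to_matrix(rows)
    if fmt == "phylip":
        ns, nc = (int(x) for x in lines[0].split())
        rows = []
        for ln in lines[1:]:
            name, states = ln.split(None, 1)
            rows.append((name, states))
        if len(rows) != ns or any(len(st) != nc for _, st in rows):
            raise ValueError("PHYLIP dimensions do not match matrix body")
        return _rows_to_matrix(rows)
    raise ValueError(f"unknown matrix format {fmt!r}")
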