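"""WHO ATC code handling for glucose-lowering drug classification.

The ATC hierarchy matters at three depths here: ``A10`` (drugs used in
diabetes), ``A10A`` (insulins), ``A10BB`` (sulfonylureas) and the
5-character chemical subgroup (e.g. ``A10BA`` biguanides) used as the unit
of drug identity.  Sulfonylureas and insulins are the two classes
associated with severe hypoglycemia under the Dutch T2D guidelines; every
other A10 subgroup counts as "other" glucose-lowering medication.

Fixed-dose combination products (``A10BD``) are decomposed into their
constituent subgroups via a shipped, editable lookup table so that e.g. a
metformin/sulfonylurea combination tablet contributes sulfonylurea
exposure.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

import pandas as pd

INSULIN = "INSULIN"
SU = "SU"
OTHER_GLD = "OTHER_GLD"
NON_GLD = "NON_GLD"

GLD_CLASSES = (INSULIN, SU, OTHER_GLD)

_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


def is_valid_atc(code: str) -> bool:
    """True for a syntactically valid 7-character ATC code."""
    return isinstance(code, str) and bool(_ATC_RE.match(code))


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("gldtraj.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, dtype=str)


@lru_cache(maxsize=1)
def class_prefix_table() -> tuple[tuple[str, str], ...]:
    """(prefix, class) pairs, longest prefix first, from the shipped table."""
    df = _read_packaged_csv("atc_classes.csv")
    rows = sorted(df.itertuples(index=False), key=lambda r: -len(r.prefix))
    return tuple((r.prefix, r.drug_class) for r in rows)


@lru_cache(maxsize=1)
def combination_constituents() -> dict[str, tuple[str, ...]]:
    """Mapping of A10BD fixed-dose combination codes to constituent subgroups."""
    df = _read_packaged_csv("a10bd_constituents.csv")
    return {
        r.atc_code: tuple(r.constituent_subgroups.split(";"))
        for r in df.itertuples(index=False)
    }


@lru_cache(maxsize=4096)
def drug_class(code: str) -> str:
    """Classify one ATC code as INSULIN / SU / OTHER_GLD / NON_GLD.

    Pure function of the code string; longest matching prefix from the
    shipped class table wins, anything unmatched is NON_GLD.
    """
    if not is_valid_atc(code):
        raise ValueError(f"not a valid 7-character ATC code: {code!r}")
    for prefix, cls in class_prefix_table():
        if code.startswith(prefix):
            return cls
    return NON_GLD


def subgroups(code: str) -> tuple[str, ...]:
    """Active 5-character subgroup(s) contributed by a dispensed code.

    A plain code contributes its own ATC-5 prefix; an A10BD combination
    product contributes the subgroups of its constituents.
    """
    if not is_valid_atc(code):
        raise ValueError(f"not a valid 7-character ATC code: {code!r}")
    if code.startswith("A10BD"):
        parts = combination_constituents().get(code)
        if parts is not None:
            return parts
    return (code[:5],)


def is_gld(code: str) -> bool:
    return code.startswith("A10")
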