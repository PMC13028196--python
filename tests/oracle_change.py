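"""Independent brute-force rule oracle for interval classification.

Works on symbolic drug names over the four-drug universe used by the
exhaustive enumeration (metformin, SU, insulin, DPP4), written directly
from the clinical rules: the state is decided by what happened to the
hypoglycemia-associated classes (SU, insulin), with insulin dominating
SU in mixed moves, switches recognised when the dropped (added) class is
replaced by (replaces) a non-SU agent, and the Mono/Comb prefix taken
from the number of drug classes at the start of the interval.
"""

HYPO = {"su", "ins"}
NON_SU = {"met", "dpp4"}  # non-insulin, non-SU agents


def oracle_classify(prev: set[str], nxt: set[str]) -> tuple[str, str]:
    added = nxt - prev
    removed = prev - nxt
    hypo_added = added & HYPO
    hypo_removed = removed & HYPO

    if not hypo_added and not hypo_removed:
        return "NC", "none"

    prefix = "Comb" if len(prev) >= 2 else "Mono"
    nonsu_added = bool(added & NON_SU)
    nonsu_removed = bool(removed & NON_SU)

    if hypo_added and not hypo_removed:
        if "ins" in hypo_added:
            if nonsu_removed:
                return "IN", f"{prefix}—Switching from non-SU to insulin"
            return "IN", f"{prefix}—Addition of insulin"
        if nonsu_removed:
            return "IN", f"{prefix}—Switching from non-SU to SU"
        return "IN", f"{prefix}—Addition of SU"

    if hypo_removed and not hypo_added:
        drug = "insulin" if "ins" in hypo_removed else "SU"
        if nonsu_added:
            return "DI", f"{prefix}—Switching from {drug} to non-SU"
        return "DI", f"{prefix}—Discontinuation of {drug}"

    # one hypo class in, the other out: insulin direction wins
    if "ins" in hypo_added:
        return "IN", f"{prefix}—Switching from SU to insulin"
    return "DI", f"{prefix}—Switching from insulin to SU"
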