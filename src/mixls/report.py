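"""Plain-text report blocks in the classic four-column layout:

    Variable  Estimate  AsymStdError  z-value  p-value

with 5-decimal fixed-width numbers, section headers, and the information
criteria on the ``LL - p`` / ``LL - p ln(N)/2`` convention.
"""

from __future__ import annotations

import numpy as np

_NAME_W = 25
_NUM_W = 12


def _num(x):
    return f"{x:<{_NUM_W}.5f}"


def format_report_table(table, sections=True):
    """Fixed-width text block from a (section,) name/estimate/se/z/p table.

    Empty input yields an empty string; sections appear in first-occurrence
    order and empty sections are omitted by construction.
    """
    if len(table) == 0:
        return ""
    lines = [f"{'Variable':<{_NAME_W}} {'Estimate':<{_NUM_W}} "
             f"{'AsymStdError':<{_NUM_W}} {'z-value':<{_NUM_W}} "
             f"{'p-value':<{_NUM_W}}",
             "-" * _NAME_W + (" " + "-" * _NUM_W) * 4]
    last_section = object()
    for _, row in table.iterrows():
        if sections and "section" in table.columns \
                and row["section"] != last_section:
            lines.append(str(row["section"]))
            last_section = row["section"]
        lines.append(f"{row['name']:<{_NAME_W}} {_num(row['estimate'])} "
                     f"{_num(row['se'])} {_num(row['z'])} {_num(row['p'])}")
    return "\n".join(lines)


def format_stage1_results(res):
    head = [f"Log Likelihood = {res.loglik:.3f}",
            f"Akaike's Information Criterion = {res.aic:.3f}",
            f"Schwarz's Bayesian Criterion = {res.bic:.3f}",
            ""]
    return "\n".join(head) + format_report_table(res.table) + "\n"


def format_stage1_chain(final):
    blocks = []
    for k, sub in enumerate(final.submodel_chain, start=1):
        blocks.append(f"==== Sub-model {k}: {sub.stage_label} ====\n"
                      + format_stage1_results(sub))
    return "\n".join(blocks)


def format_stage2_results(res):
    head = [f"Average Log Likelihood = {res.avg_loglik:.3f} "
            f"(sd= {res.loglik_sd:.3f})",
            f"Akaike's Information Criterion = {res.aic:.3f}",
            f"Schwarz's Bayesian Criterion = {res.bic:.3f}",
            ""]
    return "\n".join(head) + format_report_table(res.table, sections=False) \
        + "\n"


def format_descriptives(frame, variables, label):
    """n / mean / SD / min / max block for the listed variables."""
    lines = [f"Descriptive statistics ({label})",
             f"{'Variable':<{_NAME_W}} {'n':<8} {'Mean':<{_NUM_W}} "
             f"{'SD':<{_NUM_W}} {'Min':<{_NUM_W}} {'Max':<{_NUM_W}}"]
    for v in variables:
        x = np.asarray(frame[v], float)
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        lines.append(f"{v:<{_NAME_W}} {len(x):<8d} {_num(x.mean())} "
                     f"{_num(sd)} {_num(x.min())} {_num(x.max())}")
    return "\n".join(lines) + "\n"
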