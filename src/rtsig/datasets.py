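"""Worked-example data shipped with the package.

``example_m1a_profile`` returns ten published profile rows for m1A positions
in *S. cerevisiae* total tRNA, reverse transcribed with EpiScript under the
standard Mg2+ (3 mM) buffer. They are the canonical worked example for the
profile-file schema: the coverage column equals the sum of the ten
orientation-split base counters on every row, and the mismatch rate equals
``(cov - matches) / cov`` at the printed 5-decimal precision, which pins down
the N-base convention (N counts as a mismatch and stays in the denominator).
"""

from __future__ import annotations

from .io_formats import profile_from_string
from .types import PositionProfile

_HEADER = (
    "ref_seg\tmod\tpos\tref_base\tcov\tpre_base\tmism_rate\t"
    "A\tG\tT\tC\tN\ta\tg\tt\tc\tn\t"
    "single_jump_rate_direct\tsingle_jump_rate_delayed\tdouble_jump_rate\tarrest_rate"
)

_ROWS = """\
tdbR00000369|Saccharomyces_cerevisiae|4932|Arg|ACG\tm1A\t58\tA\t167\tG\t0.94012\t10\t39\t24\t7\t0\t0\t58\t25\t4\t0\t0.00000\t0.01754\t0.01754\t0.23661
tdbR00000370|Saccharomyces_cerevisiae|4932|Arg|TCT\tm1A\t57\tA\t25\tC\t0.52000\t12\t0\t0\t6\t1\t0\t0\t0\t6\t0\t0.00000\t0.00000\t0.00000\t0.03846
tdbR00000300|Saccharomyces_cerevisiae|4932|Asn|GTT\tm1A\t59\tA\t553\tC\t0.93671\t35\t4\t7\t229\t1\t0\t5\t11\t261\t0\t0.00318\t0.08493\t0.40552\t0.09519
tdbR00000021|Saccharomyces_cerevisiae|4932|Cys|GCA\tm1A\t57\tA\t562\tT\t0.94128\t33\t12\t205\t17\t2\t0\t18\t266\t9\t0\t0.00000\t0.00000\t0.00858\t0.09048
tdbR00000170|Saccharomyces_cerevisiae|4932|Ile|AAT\tm1A\t59\tA\t1177\tT\t0.96517\t41\t15\t447\t74\t4\t0\t16\t540\t40\t0\t0.00168\t0.00168\t0.00587\t0.23181
tdbM00000006|Saccharomyces_cerevisiae|4932|Ile|TAT\tm1A\t58\tA\t447\tT\t0.85682\t64\t15\t138\t23\t1\t0\t25\t161\t20\t0\t0.00000\t0.00665\t0.00000\t0.46437
tdbR00000251|Saccharomyces_cerevisiae|4932|Leu|TAA\tm1A\t69\tA\t571\tA\t0.35902\t366\t16\t58\t57\t1\t0\t13\t37\t23\t0\t0.00520\t0.00000\t0.00173\t0.43098
tdbR00000250|Saccharomyces_cerevisiae|4932|Leu|TAG\tm1A\t67\tA\t544\tA\t0.55699\t241\t17\t96\t41\t2\t0\t22\t87\t38\t0\t0.01961\t0.00000\t0.00713\t0.26988
tdbR00000192|Saccharomyces_cerevisiae|4932|Lys|CTT\tm1A\t58\tA\t604\tG\t0.72682\t165\t90\t85\t12\t2\t0\t127\t114\t9\t0\t0.03343\t0.00304\t0.04407\t0.17955
tdbR00000193|Saccharomyces_cerevisiae|4932|Lys|TTT\tm1A\t58\tA\t257\tG\t0.86381\t35\t36\t53\t9\t1\t0\t46\t69\t8\t0\t0.07190\t0.00000\t0.06863\t0.19895
"""

EXAMPLE_M1A_PROFILE_TSV = _HEADER + "\n" + _ROWS


def example_m1a_profile(validate: bool = True) -> list[PositionProfile]:
    """The ten-row worked-example profile (m1A positions, EpiScript, Mg2+)."""
    return profile_from_string(EXAMPLE_M1A_PROFILE_TSV, validate=validate)
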