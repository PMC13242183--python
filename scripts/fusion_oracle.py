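"""Arbitrary-precision oracle for the fusion worked values.

Evaluates the fusion sharpness alpha = |e^accC - e^accR| * k and the softmax
weights w_R, w_C at 50 decimal digits with sympy, independently of the
package's float implementation.  Run before the main build to freeze the
expected values used in the tests:

    python scripts/fusion_oracle.py
"""

import sympy as sp


def oracle(acc_rna, acc_cnv, k, digits=50):
    acc_rna, acc_cnv, k = sp.Rational(str(acc_rna)), sp.Rational(str(acc_cnv)), sp.Rational(str(k))
    alpha = sp.Abs(sp.exp(acc_cnv) - sp.exp(acc_rna)) * k
    e_r = sp.exp(alpha * acc_rna)
    e_c = sp.exp(alpha * acc_cnv)
    w_rna = e_r / (e_r + e_c)
    return sp.N(alpha, digits), sp.N(w_rna, digits), sp.N(1 - w_rna, digits)


CASES = [
    # (acc_rna, acc_cnv, k) — the first row uses the benchmark train accuracies
    # of the strongest model on the two modalities (0.954 vs 0.892) at k=10
    ("0.954", "0.892", 10),
    ("1.0", "0.5", 10),
    ("0.9", "0.9", 10),
]

if __name__ == "__main__":
    for acc_r, acc_c, k in CASES:
        alpha, w_r, w_c = oracle(acc_r, acc_c, k)
        print(f"acc_rna={acc_r} acc_cnv={acc_c} k={k}")
        print(f"  alpha = {alpha}")
        print(f"  w_rna = {w_r}")
        print(f"  w_cnv = {w_c}")
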