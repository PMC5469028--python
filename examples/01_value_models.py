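"""Subjective value and choice probability for one delayed offer.

Builds a single intertemporal offer (65 euros in 45 days vs. 20 euros now)
and prints its value under the three discount functions plus the softmax
choice probability at a moderate decision temperature.
"""

from discountfit import (
    indifference_amount, p_choose_ll_softmax, sv_constant_sensitivity,
    sv_exponential, sv_hyperbolic,
)

amount, delay = 65.0, 45.0
k, s, beta = 0.02, 0.8, 3.0

sv_h = sv_hyperbolic(amount, delay, k)
sv_e = sv_exponential(amount, delay, k)
sv_c = sv_constant_sensitivity(amount, delay, k, s)

print(f"offer: {amount:.0f} EUR in {delay:.0f} d vs. 20 EUR now (k={k}/day)")
print(f"  hyperbolic SV           = {sv_h:6.2f} EUR")
print(f"  exponential SV          = {sv_e:6.2f} EUR")
print(f"  constant-sensitivity SV = {sv_c:6.2f} EUR (s={s})")
print(f"  P(choose delayed | hyperbolic, beta={beta}) = "
      f"{p_choose_ll_softmax(sv_h, 20.0, beta):.3f}")
print(f"  indifference amount at {delay:.0f} d = "
      f"{indifference_amount(k, delay):.2f} EUR")
print("A subjective value above 20 EUR makes the delayed option the better "
      "one; the softmax turns the value difference into a choice probability.")
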