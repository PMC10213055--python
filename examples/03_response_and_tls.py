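"""Pathological response classification and TLS density.

Reconstructs the two-arm response table of a neoadjuvant NSCLC cohort
(chemotherapy alone vs chemotherapy + PD-1 blockade) from per-patient
viable-tumor percentages, prints the per-arm MPR/pCR rates and the
chi-square comparing the arms, and shows the TLS density computation.
"""

from tilspatial import (
    ResponseCall,
    TLSAnnotation,
    arm_response_rates,
    chi_square_test,
    classify_response,
    tls_density,
)

calls, arms = [], {}
for n, viable, arm in [
    (24, 50.0, "NAC"),   # non-MPR
    (6, 5.0, "NAC"),     # MPR
    (12, 40.0, "NAPC"),  # non-MPR
    (7, 5.0, "NAPC"),    # MPR without pCR
    (16, 0.0, "NAPC"),   # pCR (0% viable tumor)
]:
    for _ in range(n):
        pid = f"p{len(calls)}"
        calls.append(ResponseCall(pid, viable, classify_response(viable)))
        arms[pid] = arm

rates = arm_response_rates(calls, arms)
print(rates.to_string(index=False))
t = rates.set_index("arm")
chi = chi_square_test(
    [
        [int(t.loc["NAC", "n"] - t.loc["NAC", "n_mpr"]), int(t.loc["NAC", "n_mpr"])],
        [int(t.loc["NAPC", "n"] - t.loc["NAPC", "n_mpr"]), int(t.loc["NAPC", "n_mpr"])],
    ]
)
print(f"\nMPR vs arm chi-square = {chi.statistic:.3f}, p = {chi.p_value:.2e}")
print("MPR means <= 10% mean viable tumor across slides; pCR means 0% and "
      "counts toward the MPR rate.")

ann = TLSAnnotation("patient1_post", tls_count=3, evaluated_area_mm2=2.0)
print(f"\nTLS density: {ann.tls_count} structures / "
      f"{ann.evaluated_area_mm2} mm^2 = {tls_density(ann):.2f} per mm^2")
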