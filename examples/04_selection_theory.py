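"""Response-to-selection calculus of the two-step genomic selection program.

Reproduces the program's arithmetic: finite-population selection
intensities for the F2 and F5:6 selection steps, the 1/2 and 7/8 deflation
of the usable GCA standard deviation, and the total expected response.
"""

from rrgskit import selection

i1 = selection.selection_intensity(60, 629)
i2 = selection.selection_intensity(50, 382)
print(f"selection intensities: i(60, 629) = {i1:.2f}, i(50, 382) = {i2:.2f}")

sd_f2 = selection.gca_sd_f2(2.88)   # half the base GCA variance segregates
sd_f56 = selection.gca_sd_f56(sd_f2)  # selfing releases 7/8 of the remainder
print(f"usable GCA standard deviation: F2 stage {sd_f2:.2f}, "
      f"F5:6 stage {sd_f56:.2f} dt/ha")

h = selection.mean_accuracy([0.55, 0.76])  # mean of T1/T2 abilities
steps = [
    selection.SelectionStep(60, 629, h=h, sigma_a=sd_f2),
    selection.SelectionStep(50, 382, h=h, sigma_a=sd_f56),
]
rep = selection.expected_response(steps)
print(f"expected response: step 1 {rep.step_responses[0]:.2f} + "
      f"step 2 {rep.step_responses[1]:.2f} = {rep.total_expected:.2f} dt/ha")

r_obs = selection.observed_response(91.0, 90.0)
print(f"an observed differential of {r_obs:.1f} dt/ha against an expected "
      f"{rep.total_expected:.1f} illustrates how strongly environment shifts "
      "can deflate realized gain")

thr = selection.fixation_threshold(-2.0)
print(f"under negative overdominance k = -2, the favourable allele is fixed "
      f"only if it already exceeds frequency {thr:.2f}")
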