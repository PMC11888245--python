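"""Single-field calibration: tune-mix arrival times -> CCS conversion.

Calibrant ions with accepted reference CCS values define the linear
relation t_A = beta * (sqrt(mu)/z) * CCS + t_fix.  Once beta and the
instrument dead time t_fix are fitted, any unknown ion's arrival time
converts to a CCS.  Here the tune mix is generated from a known forward
model, so the fit recovers it exactly (r^2 = 1).
"""

from ccslib import drift_to_ccs, fit_single_field
from ccslib.synthetic import generate_tune_mix

calibrants = generate_tune_mix((0.21, 0.20))  # true beta, t_fix
cal = fit_single_field(calibrants)
print(f"fitted beta  = {cal.beta:.6f} ms/(A^2 sqrt(Da))")
print(f"fitted t_fix = {cal.t_fix:.6f} ms (instrument dead time)")
print(f"r^2 = {cal.r_squared:.10f} over {cal.n_calibrants} calibrants")

t_a, mz = 204.3, 400.0
ccs = drift_to_ccs(t_a, mz, 1, cal)
print(f"an ion at m/z {mz}, arrival time {t_a} ms -> CCS {ccs:.2f} A^2")
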