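"""Fit a Hill dose-response curve and read off the IC50.

Simulates triplicate fitness measurements along a 1.5-fold dilution series
(plus vehicle) for a compound whose true IC50 is 8.6 mM with Hill slope 2,
then recovers the IC50 by least squares.
"""

from chemscreen import fit_dose_response, simulate_dose_response_fitness

TRUTH_MM = 8.6
doses = [0.0] + sorted(8 * TRUTH_MM / 1.5**i for i in range(11))
d, f = simulate_dose_response_fitness(
    ic50=TRUTH_MM, hill=2.0, floor=0.05, doses=doses, sd=0.05, replicates=3, seed=1
)
dr = fit_dose_response(d, f)

print(f"true IC50    : {TRUTH_MM} mM")
print(f"fitted IC50  : {dr.ic50:.2f} mM")
print(f"Hill slope   : {dr.hill:.2f}")
print(f"floor        : {dr.floor:.3f}")
print(f"RMS residual : {dr.residual:.3f}")
print(
    "\nThe IC50 is the dose halving fitness relative to vehicle; the floor"
    "\nis the residual fitness at saturating dose."
)
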