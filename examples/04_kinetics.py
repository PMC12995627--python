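"""Post-cryoablation time-course analysis.

The packaged longitudinal mRNA panel (fold change vs the pre-procedure
baseline T0) shows a pulse-shaped response for every analyte: peak around
8-12 h (T2) and return toward baseline by 1-3 months.
"""

from pyrosig import detect_peak, load_paper_fixture, time_to_baseline
from pyrosig.kinetics import series_from_fixture

panel = series_from_fixture(load_paper_fixture("table5"), level="mrna_fc")
print(f"{'analyte':<8} {'peak':>5} {'value':>6} {'back to baseline':>17}")
for series in panel:
    peak_t, peak_v = detect_peak(series)
    back = time_to_baseline(series, band=0.15) or "never"
    print(f"{series.analyte:<8} {peak_t:>5} {peak_v:>6.2f} {back:>17}")
print("\n'back to baseline' = earliest post-peak point within 15% of"
      " baseline with all later points staying inside the band.")
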