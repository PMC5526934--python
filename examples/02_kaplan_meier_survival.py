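"""Staggered-entry Kaplan-Meier survival on a small hand-built collar history.

Eight collared females over one biological year (1 Apr - 31 Mar): two die,
one is censored when her collar is removed, and two enter mid-year. The
printed estimate is the product over death times of (1 - deaths / at-risk),
with the at-risk pool respecting entry and censoring dates.
"""

import datetime as dt

from caribou_pva import CollarRecord, km_annual_survival

d = dt.date.fromisoformat
records = [
    CollarRecord("A", "demo", d("2005-04-01"), d("2006-03-31"), "alive_at_year_end"),
    CollarRecord("B", "demo", d("2005-04-01"), d("2005-08-01"), "dead"),
    CollarRecord("C", "demo", d("2005-06-01"), d("2006-03-31"), "alive_at_year_end"),
    CollarRecord("D", "demo", d("2005-06-01"), d("2005-10-01"), "censored"),
    CollarRecord("E", "demo", d("2005-04-01"), d("2006-03-31"), "alive_at_year_end"),
    CollarRecord("F", "demo", d("2005-04-01"), d("2006-03-31"), "alive_at_year_end"),
    CollarRecord("G", "demo", d("2005-04-01"), d("2006-03-31"), "alive_at_year_end"),
    CollarRecord("H", "demo", d("2005-07-01"), d("2005-12-01"), "dead"),
]

est = km_annual_survival(records, "demo", 2005)
print(f"annual survival {est.S_hat:.4f} "
      f"({est.n_deaths} deaths among {est.n_females} monitored females)")
print("by hand: (1 - 1/8) * (1 - 1/6) = 35/48 =", 35 / 48)
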