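"""Method-comparison statistics on the bundled clinical cohort tables:
Passing-Bablok regression, Spearman rank correlation and R^2 between
the standard-protocol Ki and the short-protocol Ki,s."""

from petki.cohort_tables import method_comparison_report

report = method_comparison_report()
print(report.to_frame().to_string(index=False))
print()
print(f"Passing-Bablok slope 95% CI     : "
      f"({report.pb_slope_ci[0]:.3f}, {report.pb_slope_ci[1]:.3f})")
print(f"Passing-Bablok intercept 95% CI : "
      f"({report.pb_intercept_ci[0]:.4f}, {report.pb_intercept_ci[1]:.4f})")
print()
print("A slope indistinguishable from 1 and an intercept indistinguishable")
print("from 0 mean the short protocol is interchangeable with the standard")
print("60-min acquisition for regional Ki quantification.")
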