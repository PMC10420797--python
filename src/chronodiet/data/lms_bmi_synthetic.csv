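# Synthetic LMS BMI-for-age reference (NOT an official growth chart).
# Smooth curves in the range of published adolescent references, shipped so
# the pipeline runs self-contained; replace with an official chart via the
# lms_path configuration for real analyses. sex: 1 female, 2 male.
sex,age_months,L,M,S
1,192,-1.80,20.40,0.130
1,198,-1.82,20.55,0.130
1,204,-1.84,20.68,0.131
1,210,-1.86,20.80,0.131
1,216,-1.88,20.90,0.132
1,222,-1.90,20.98,0.132
1,228,-1.92,21.05,0.133
2,192,-2.20,20.50,0.125
2,198,-2.22,20.85,0.126
2,204,-2.24,21.18,0.126
2,210,-2.26,21.48,0.127
2,216,-2.28,21.75,0.127
2,222,-2.30,22.00,0.128
2,228,-2.32,22.20,0.128
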