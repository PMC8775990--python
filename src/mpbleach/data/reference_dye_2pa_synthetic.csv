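# SYNTHETIC stand-in for a corrected reference-dye two-photon absorption
# spectrum (Rhodamine-6G-like smooth shape, arbitrary but fixed).  It is NOT
# measured data: substitute a published, instrument-matched reference
# spectrum for quantitative calibration work (source: synthetic, this
# package).
lambda_nm,sigma2_GM
700,12.0
750,18.0
800,28.0
850,36.0
900,30.0
950,22.0
1000,15.0
1050,11.0
1100,9.0
1150,8.0
1200,7.5
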