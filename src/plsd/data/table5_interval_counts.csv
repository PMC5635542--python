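# CRCs by months from last cancer-free colonoscopy to diagnosis, per series.
# The non-Finnish 36-41 count is stored as 2 (not the printed 3) so that the
# published cumulative column (...35, 37, 40, 50) and the series total of 50
# CRCs are internally consistent.
series,bin,count
finnish,<6,0
finnish,7-11,2
finnish,12-17,3
finnish,18-23,4
finnish,24-29,17
finnish,30-35,3
finnish,36-41,14
finnish,42-47,3
finnish,48-120,5
other,<6,0
other,7-11,5
other,12-17,13
other,18-23,7
other,24-29,6
other,30-35,4
other,36-41,2
other,42-47,3
other,48-120,10
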