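lncrna_id	classification	target_id	correlation
TCONS_00043396	lincRNA	sjCRY-DASH	0.999986
TCONS_00017519	lincRNA	sjCRY-DASH	0.999975
TCONS_00009907	lincRNA	sjCRY-DASH	0.999995
TCONS_00008371	lincRNA	sjCRY-DASH	0.999993
TCONS_00008286	lincRNA	sjCRY-DASH	0.999996
TCONS_00006247	lincRNA	sjCRY-DASH	0.999996
TCONS_00002718	lincRNA	sjCRY-DASH	0.999996
TCONS_00001280	lincRNA	sjCRY-DASH	0.999998
TCONS_00043393	lincRNA	sjCRY-DASH	0.99999
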