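(((t1:0.0672717696,t2:0.0672717696):0.106783874,(t3:0.1512873671,t4:0.1512873671):0.0227682765):0.0259443564,(t5:0.1107991739,(t6:0.0882650103,(t7:0.0481502827,t8:0.0481502827):0.0401147276):0.0225341635):0.0892008261);
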