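allele	tier	function	rsid	position	ref	alt
*38	1	normal	.	.	.	.
*1	2	normal	rs3758581	94852738	A	G
*2	1	no_function	rs4244285	94781859	G	A
*3	1	no_function	rs4986893	94780653	G	A
*4	2	no_function	rs28399504	94762706	A	G
*8	2	no_function	rs41291556	94775367	T	C
*17	1	increased	rs12248560	94761900	C	T
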