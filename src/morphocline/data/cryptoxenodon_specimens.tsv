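database	country	coden	altitude_m	latitude	states
FAS579*	Brazil	ES	513	20°17'02.6"S	000010015130000030202000
FAS4607	Brazil	PA	17	01°44'12.8"S	100010100100010000000110
FAS4611	Brazil	PA	36	01°44'14.0"S	000110100000110140100110
FAS4613	Brazil	PA	36	01°44'14.0"S	100111100000010020000110
FAS4614	Brazil	BA	52	14°46'00.0"S	100020103020010050010000
FAS4602	French Guiana	GUI	61	04°43'22.22"N	000020110100011050010002
FAS4603	French Guiana	GUI	61	04°43'22.22"N	000121113100001230210010
FAS4605	Colombia	COL	75	01°55'00.0"S	000111100020102151110110
FAS4604	French Guiana	GUI	80	04°02'00.0"N	001020110100101051010001
UFES45852	Brazil	BA	89	14°20'48.0"S	000010210100000041010010
UFES45885	Brazil	BA	89	14°42'69.0"S	100010100000010021010010
FAS4600	Brazil	AM	111	02°57'48.3"S	100011100000101041010110
FAS4601	Brazil	AM	111	02°57'48.3"S	010100100101001110010010
UFES45548	Brazil	BA	115	14°34'30.0"S	001011101011000050111110
UFES49155	Brazil	BA	123	14°56'49.0"S	001011210100010050110110
UFES49176	Brazil	BA	354	14°59'51.0"S	001021110100000001110002
INPA	Brazil	AM	416	03°44'45.0"S	000021103020001040110110
FAS333	Brazil	ES	501	20°16'54.4"S	000021212201000050110002
FAS1165	Brazil	ES	513	20°17'02.6"S	000011220221000051110002
FAS1124	Brazil	ES	557	20°17'19.9"S	001021213221000041110002
FAS331	Brazil	ES	561	20°17'26.4"S	001021224241100051210002
FAS1127	Brazil	ES	561	20°17'26.4"S	001021220201101051110002
UFES49039	Brazil	ES	714	20°27'53.0"S	001021110101000051010002
UFES49049	Brazil	ES	714	20°27'53.0"S	001021222231100051010002
FAS1129	Brazil	ES	775	19°55'16.4"S	000021220221000051110001
FAS1128	Brazil	ES	789	19°53'41.0"S	000021212231000051210002
UFES41704	Brazil	ES	790	20°02'31.1"S	001021213221000041210002
UFES41705	Brazil	ES	790	20°02'31.1"S	001021112131000050210001
AMNH156	Venezuela	VNZ	1135	03°30'48.0"N	100101103041012150010000
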