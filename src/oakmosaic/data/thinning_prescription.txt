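#Management Area ID#	8
#Ranking algorithm for stand selection:1is random stand selection, 6 is highest average basal area#	6
#Entry year#	5
#Reentry year#	5
#Minimum stand harvest basal area (m^2^)#	18.36
#remove largest tree first#	1
#Proportion of management area to harvest#	0.03
#Target stand basal area (m^2^)#	18.36
#Species priority ranking for harvest#
#Pine#	6
#Black oak#	3
#Red oak#	4
#White oak#	5
#Hickory#	1
#Maple#	2
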