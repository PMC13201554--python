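cell00001
cell00002
cell00003
cell00004
cell00005
cell00006
cell00007
cell00008
cell00009
cell00010
cell00011
cell00012
cell00013
cell00014
cell00015
cell00016
cell00017
cell00018
cell00019
cell00020
cell00021
cell00022
cell00023
cell00024
cell00025
cell00026
cell00027
cell00028
cell00029
cell00030
cell00031
cell00032
cell00033
cell00034
cell00035
cell00036
cell00037
cell00038
cell00039
cell00040
cell00041
cell00042
cell00043
cell00044
cell00045
cell00046
cell00047
cell00048
cell00049
cell00050
cell00051
cell00052
cell00053
cell00054
cell00055
cell00056
cell00057
cell00058
cell00059
cell00060
cell00061
cell00062
cell00063
cell00064
cell00065
cell00066
cell00067
cell00068
cell00069
cell00070
cell00071
cell00072
cell00073
cell00074
cell00075
cell00076
cell00077
cell00078
cell00079
cell00080
cell00081
cell00082
cell00083
cell00084
cell00085
cell00086
cell00087
cell00088
cell00089
cell00090
cell00091
cell00092
cell00093
cell00094
cell00095
cell00096
cell00097
cell00098
cell00099
cell00100
cell00101
cell00102
cell00103
cell00104
cell00105
cell00106
cell00107
cell00108
cell00109
cell00110
cell00111
cell00112
cell00113
cell00114
cell00115
cell00116
cell00117
cell00118
cell00119
cell00120
cell00121
cell00122
cell00123
cell00124
cell00125
cell00126
cell00127
cell00128
cell00129
cell00130
cell00131
cell00132
cell00133
cell00134
cell00135
cell00136
cell00137
cell00138
cell00139
cell00140
cell00141
cell00142
cell00143
cell00144
cell00145
cell00146
cell00147
cell00148
cell00149
cell00150
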