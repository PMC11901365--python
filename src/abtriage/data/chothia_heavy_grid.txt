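# Canonical heavy-chain Chothia grid: 113 base positions, fixed 82A-C,
# insertion slots 31A-B, 52A-C, 100A-K. One label per line, grid order.
H1
H2
H3
H4
H5
H6
H7
H8
H9
H10
H11
H12
H13
H14
H15
H16
H17
H18
H19
H20
H21
H22
H23
H24
H25
H26
H27
H28
H29
H30
H31
H31A
H31B
H32
H33
H34
H35
H36
H37
H38
H39
H40
H41
H42
H43
H44
H45
H46
H47
H48
H49
H50
H51
H52
H52A
H52B
H52C
H53
H54
H55
H56
H57
H58
H59
H60
H61
H62
H63
H64
H65
H66
H67
H68
H69
H70
H71
H72
H73
H74
H75
H76
H77
H78
H79
H80
H81
H82
H82A
H82B
H82C
H83
H84
H85
H86
H87
H88
H89
H90
H91
H92
H93
H94
H95
H96
H97
H98
H99
H100
H100A
H100B
H100C
H100D
H100E
H100F
H100G
H100H
H100I
H100J
H100K
H101
H102
H103
H104
H105
H106
H107
H108
H109
H110
H111
H112
H113
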