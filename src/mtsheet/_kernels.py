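"""Scalar energy/gradient kernels for the angular interaction terms.

GENERATED by tools/generate_kernels.py -- do not edit by hand.

Each function returns ``(angle, energy, dE/dq...)`` for one interaction
term, with one gradient component per input coordinate in argument order.
A small epsilon (1e-12) regularises every normalisation so degenerate
(collinear) geometries give damped, finite gradients instead of NaNs.
"""

import math

__all__ = ["bend_term", "dih_long_term", "dih_lat_term",
           "dih_long_axis_term", "dih_lat_axis_term"]



def bend_term(ax, ay, az, bx, by, bz, cx, cy, cz, kk, t0):
    """Supplementary bend angle at B for (A, B, C); E = kk/2 (theta-t0)^2."""
    t1 = ax - bx
    t2 = -cy
    t3 = by + t2
    t4 = ay - by
    t5 = -cx
    t6 = bx + t5
    t7 = t1*t3 - t4*t6
    t8 = -cz
    t9 = bz + t8
    t10 = az - bz
    t11 = -t10*t3 + t4*t9
    t12 = -t7
    t13 = -t9
    t14 = -t6
    t15 = t1*t13 - t10*t14
    t16 = -t11
    t17 = t12**2 + t15**2 + t16**2 + 1.0e-12
    t18 = math.sqrt(t17)
    t19 = t1*t14 + t10*t13 - t3*t4
    t20 = t0 - math.atan2(t18, -t19)
    t21 = 1/t18
    t22 = t19*t21
    t23 = kk*t20/(t17 + t19**2)
    t24 = ay + t2
    t25 = az + t8
    t26 = ax + t5
    return (math.atan2(math.sqrt(t11**2 + t7**2 + (-t1*t9 + t10*t6)**2 + 1.0e-12), t1*t6 + t10*t9 + t3*t4),
            (1/2)*kk*t20**2,
            t23*(t18*t6 - t22*(t12*t3 + t15*t9)),
            t23*(t18*t3 + t22*(t12*t6 - t16*t9)),
            t23*(t18*t9 + t22*(t15*t6 + t16*t3)),
            t23*(t18*(ax - 2*bx + cx) + t22*(t12*t24 + t15*t25)),
            t23*(t18*(ay - 2*by + cy) + t22*(-t12*t26 + t16*t25)),
            t23*(t18*(az - 2*bz + cz) - t22*(t15*t26 + t16*t24)),
            -t23*(t1*t18 + t22*(t10*t15 + t12*t4)),
            t23*(-t18*t4 + t19*t21*(t1*t12 - t10*t16)),
            t23*(-t10*t18 + t19*t21*(t1*t15 + t16*t4)))



def dih_long_term(ax, ay, az, bx, by, bz, cx, cy, cz, lx, ly, lz, kk, sgn):
    """Signed longitudinal dihedral for (A, B, C) with lateral reference L."""
    t0 = ax - bx
    t1 = t0**2
    t2 = ay - by
    t3 = t2**2
    t4 = az - bz
    t5 = t3 + t4**2
    t6 = -t0
    t7 = -ly
    t8 = ay + t7
    t9 = -t8
    t10 = t6*t9
    t11 = -lx
    t12 = ax + t11
    t13 = -t12
    t14 = -t2
    t15 = t13*t14
    t16 = t10 - t15
    t17 = -t16
    t18 = -lz
    t19 = az + t18
    t20 = -t19
    t21 = t20*t6
    t22 = -t4
    t23 = t13*t22
    t24 = -t23
    t25 = t21 + t24
    t26 = t14*t20
    t27 = t22*t9
    t28 = t26 - t27
    t29 = -t28
    t30 = t17**2 + t25**2 + t29**2 + 1.0e-12
    t31 = 1/math.sqrt(t30)
    t32 = -cy
    t33 = by + t32
    t34 = -t33
    t35 = -cx
    t36 = bx + t35
    t37 = -t36
    t38 = -t14*t37 + t34*t6
    t39 = t14*t17
    t40 = t22*t25
    t41 = t39 - t40
    t42 = -cz
    t43 = bz + t42
    t44 = -t43
    t45 = t14*t44 - t22*t34
    t46 = t25*t6
    t47 = t14*t29
    t48 = t46 - t47
    t49 = t38*t41 - t45*t48
    t50 = t31*t49
    t51 = t2*t50
    t52 = t0*t19
    t53 = t12*t4
    t54 = -t53
    t55 = t52 + t54
    t56 = t0*t55
    t57 = t2*t28
    t58 = t56 + t57
    t59 = -t22*t37 + t44*t6
    t60 = t55**2 + 1.0e-12
    t61 = t16**2 + t28**2 + t60
    t62 = 1/math.sqrt(t61)
    t63 = t59*t62
    t64 = t0*t33 - t2*t36
    t65 = t17*t6
    t66 = t22*t29
    t67 = t65 - t66
    t68 = t31*t67
    t69 = t58*t63 + t64*t68
    t70 = t0*t69
    t71 = t16*t2
    t72 = t4*t55
    t73 = t71 + t72
    t74 = t2*t43 - t33*t4
    t75 = -t31*t67*t74 + t63*t73
    t76 = -t75
    t77 = t4*t76
    t78 = t0*t8 - t12*t2
    t79 = t2*t78 + t72
    t80 = t4*t8
    t81 = t19*t2 - t80
    t82 = t60 + t78**2 + t81**2
    t83 = 1/math.sqrt(t82)
    t84 = t58*t62
    t85 = t0*t43 - t36*t4
    t86 = t0*t16
    t87 = t28*t4
    t88 = t86 - t87
    t89 = 1/t61
    t90 = t58*t74 + t64*t73
    t91 = t58*t85 + t64*t88
    t92 = sgn**2
    t93 = t89*t92
    t94 = 1/t82
    t95 = t58**2*t93 + 0.01
    t96 = t92/(t79**2*t92*t94 + t88**2*t93 + t95)
    t97 = t96*(t75**2 + t89*t90**2 + t89*t91**2)
    t98 = t64**2 + t74**2 + 0.01
    t99 = kk/(t85**2 + t98)
    t100 = -t59
    t101 = 1/(t59**2 + t98)
    t102 = 1/t30
    t103 = t102*t49**2 + t69**2 + t76**2
    t104 = t101*t103
    t105 = by + t7
    t106 = -t105
    t107 = bz + t18
    t108 = t106*t17 + t107*t25
    t109 = t102*t108
    t110 = t106*t14 - t107*t22 - t109*t39 + t109*t40
    t111 = -t21 + t23
    t112 = t107*t6 - t109*t46 + t109*t47 + t111
    t113 = t43*t62
    t114 = t105*t2
    t115 = t108*t89
    t116 = t106*t6 - t109*t65 + t109*t66 + t16
    t117 = t33*t68
    t118 = -t52 + t53
    t119 = -t67
    t120 = t102*t92
    t121 = 1/(t120*t67**2 + t73**2*t93 + t95)
    t122 = t103*t120*t121
    t123 = kk*t101*t121*t92
    t124 = bx + t11
    t125 = -t107
    t126 = t124*t17 + t125*t29
    t127 = t102*t126
    t128 = t124*t14 - t127*t39 + t127*t40 + t16
    t129 = t102*t126*t14*t29 - t125*t14 - t127*t46 - t28
    t130 = t124*t6 - t125*t22 - t127*t65 + t127*t66
    t131 = -t130
    t132 = t31*t76
    t133 = t31*t64
    t134 = t126*t89
    t135 = -t26
    t136 = t135 + t27
    t137 = -t124
    t138 = t105*t29 + t137*t25
    t139 = t138*t89
    t140 = -t118 - t124*t4 - t139*t71 - t139*t72
    t141 = t102*t138
    t142 = -t105*t14 + t137*t6 - t141*t46 + t141*t47
    t143 = -t102*t138*t22*t29 + t105*t22 + t141*t65 + t28
    t144 = t62*t73
    t145 = t31*t74
    t146 = ay + t32
    t147 = -t146
    t148 = az + t42
    t149 = t17*t8 + t20*t25
    t150 = t102*t149
    t151 = t14*t8 - t150*t39 + t150*t40 - t20*t22
    t152 = -t150*t46 + t150*t47 + 2*t21 + t24
    t153 = t2*t8
    t154 = t149*t89
    t155 = -t10 + t15 - t150*t65 + t150*t66 + t6*t8
    t156 = ax + t35
    t157 = -t148
    t158 = t13*t17 + t19*t29
    t159 = t102*t158
    t160 = -t10 + t102*t158*t22*t25 + 2*t13*t14 - t159*t39
    t161 = -t102*t14*t158*t29 + t136 + t14*t19 + t159*t46
    t162 = -t161
    t163 = t13*t6 - t159*t65 + t159*t66 - t19*t22
    t164 = -t163
    t165 = -t156
    t166 = t12*t25 + t29*t9
    t167 = t102*t166
    t168 = t12*t6 - t14*t9 - t167*t46 + t167*t47
    t169 = t135 + t167*t65 - t167*t66 + 2*t27
    t170 = t62*t74
    t171 = t12*t22 + t167*t39 - t167*t40 + t25
    t172 = t166*t89
    t173 = t2*t68
    t174 = t0*t4
    t175 = -t174
    t176 = t25*t4 + t39
    t177 = t176*t89
    t178 = t175 + t177*t56 + t177*t57
    t179 = -t177*t71 - t177*t72 + t5
    t180 = t0*t2
    t181 = t62*t64
    t182 = t73*t94
    t183 = t2*t81
    t184 = t102*t176
    t185 = t14*t6 - t184*t65 + t184*t66
    t186 = t102*t67
    t187 = t58*t89
    t188 = t73*t89
    t189 = t96*t99
    t190 = t0*t17 + t66
    t191 = t102*t190
    t192 = t14*t22 + t191*t46 - t191*t47
    t193 = t0*t6 - t191*t65 + t191*t66 - t22**2
    t194 = t190*t89
    t195 = t180 + t194*t71 + t194*t72
    t196 = t2*t29 + t46
    t197 = t196*t89
    t198 = t1 + t3
    t199 = t197*t56 + t197*t57 + t198
    t200 = t102*t196
    t201 = t200*t39 - t200*t40 + t22*t6
    t202 = -t197*t86 + t197*t87 + t2*t4
    t203 = t58*t94
    return (math.atan2(sgn*(t51 + t70 - t77)/math.sqrt(t1 + t5 + 1.0e-12), sgn*t62*t85*t88 - sgn*t64*t84 + sgn*t74*t79*t83 + 1.0e-9),
            (1/2)*t97*t99,
            t123*(t102*t49*(t110*t38 - t112*t45 + t33*t41) - t104*(t100*t44 + t33*t38) - t122*(t110*t41 + t112*t48 - t116*t119) - t69*(-t113*t58 - t116*t31*t64 - t117 + t59*t62*(-t0*t107 + t115*t56 + t115*t57 + t118)) + t76*(-t113*t73 + t116*t31*t74 - t63*(t107*t4 + t114 - t115*t71 - t115*t72))),
            t123*(t102*t49*(t128*t38 - t129*t45 + t37*t41 - t43*t48) - t104*(t37*t38 + t43*t45) - t122*(t119*t131 + t128*t41 + t129*t48) - t132*(-t100*t128 + t119*t43 + t131*t45) - t69*(-t130*t133 + t36*t68 + t63*(-t107*t2 + t134*t56 + t134*t57 + t136))),
            t123*(-t104*(t100*t36 + t34*t45) - t122*(t119*t143 + t142*t48 + t41*(t102*t138*t22*t25 - t111 - t137*t22 - t141*t39)) + t31*t69*(t100*t142 - t143*t38 + t36*t48) - t50*t62*(-t140*t64 + t33*t58 + t74*(t0*t124 + t114 + t139*t56 + t139*t57)) + t76*(-t117 - t140*t63 - t143*t145 + t144*t36)),
            t123*(t102*t49*(t147*t41 + t151*t38 - t152*t45) - t104*(t100*t148 + t147*t38) - t122*(-t119*t155 + t151*t41 + t152*t48) - t69*(-t133*t155 + t146*t68 + t148*t84 + t63*(t154*t56 + t154*t57 + 2*t52 + t54)) + t76*(t144*t148 + t145*t155 + t63*(t153 + t154*t71 + t154*t72 + t19*t4))),
            t123*(t102*t49*(t156*t41 - t157*t48 + t160*t38 - t162*t45) - t104*(t156*t38 + t157*t45) - t122*(t119*t164 + t160*t41 + t162*t48) - t132*(-t100*t160 + t119*t157 + t164*t45) + t31*t69*(t156*t67 + t161*t59 + t163*t64)),
            t123*(-t104*(t100*t165 + t146*t45) - t122*(t119*t169 + t168*t48 - t171*t41) + t31*t69*(t100*t168 + t165*t48 - t169*t38) - t50*(t133*t171 - t146*t84 + t170*(-t0*t12 + t0*t166*t55*t89 - t153 + t166*t2*t28*t89)) + t76*(-t144*t156 + t146*t31*t67 - t170*(t136 + t172*t86 - t172*t87 + t80) + t171*t31*t59)),
            t123*(-t104*(t100*t22 + t2*t38) + t144*t51 - t144*t77 + t69*(t173 + t4*t84)),
            t123*(t102*t49*(-t4*t48 + t41*t6) - t104*(t38*t6 + t4*t45) + t31*t4*t67*t76 - t68*t70),
            t123*(-t104*(t0*t100 + t14*t45) - t51*t84 - t70*t84 + t76*(t0*t144 - t173)),
            t189*(-t62*t91*(-t181*(-t177*t86 + t177*t87 + t180) + t83*t85*(t175 + t182*t183 + t182*t56)) + t75*(-t145*t185 + t179*t63) + t89*t90*(-t178*t74 + t179*t64) - t97*(-t178*t187 + t179*t188 + t185*t186)),
            t189*(t31*t62*t91*(t192*t59 + t193*t64) + t62*t90*(-t181*t195 + t192*t31*t74) - t75*(t145*t193 + t195*t63) - t97*(t186*t193 - t188*t195 + t192*t31*t84)),
            t189*(-t62*(t75*(t202*t74 + t85*(t174 + t197*t71 + t197*t72)) + t90*(t133*t201 + t170*t199) + t91*(-t181*t202 + t83*t85*(-t183*t203 + t198 - t203*t56))) + t97*(t144*t201*t31 + t187*t199 - t202*t62*t68)))



def dih_lat_term(dx, dy, dz, ex, ey, ez, fx, fy, fz, px, py, pz, qx, qy, qz, kk):
    """Unsigned lateral dihedral for turn triple (D, E, F); P, Q are the axial neighbours of D and E."""
    t0 = dx - ex
    t1 = -t0
    t2 = -pz
    t3 = dz + t2
    t4 = -t3
    t5 = t1*t4
    t6 = -px
    t7 = dx + t6
    t8 = -t7
    t9 = dz - ez
    t10 = -t9
    t11 = t10*t8
    t12 = -t11 + t5
    t13 = dy - ey
    t14 = t13*t3
    t15 = -py
    t16 = dy + t15
    t17 = -t16*t9
    t18 = t14 + t17
    t19 = t0*t12 + t13*t18
    t20 = ey - fy
    t21 = ex - fx
    t22 = -qy
    t23 = ey + t22
    t24 = t21*t23
    t25 = -qx
    t26 = ex + t25
    t27 = -t20*t26
    t28 = t24 + t27
    t29 = ez - fz
    t30 = -t21
    t31 = -qz
    t32 = ez + t31
    t33 = -t32
    t34 = t30*t33
    t35 = -t26
    t36 = -t29
    t37 = t35*t36
    t38 = t34 - t37
    t39 = t20*t28 + t29*t38
    t40 = t0*t16
    t41 = -t13*t7
    t42 = t40 + t41
    t43 = t12*t9 + t13*t42
    t44 = t20*t32
    t45 = -t23*t29
    t46 = t44 + t45
    t47 = t20*t46 + t21*t38
    t48 = -t19*t39 + t43*t47
    t49 = t21*t28 - t29*t46
    t50 = t0*t42 - t18*t9
    t51 = -t19*t49 + t47*t50
    t52 = -t50
    t53 = -t20
    t54 = -t23
    t55 = t30*t54
    t56 = t35*t53
    t57 = -t56
    t58 = t55 + t57
    t59 = -t38
    t60 = -t36*t59 + t53*t58
    t61 = -t13
    t62 = -t16
    t63 = t1*t62
    t64 = t61*t8
    t65 = -t64
    t66 = t63 + t65
    t67 = -t12
    t68 = -t10*t67 + t61*t66
    t69 = -t49
    t70 = -t52*t60 + t68*t69
    t71 = t48**2 + t51**2 + t70**2
    t72 = 1/(t19**2 + t43**2 + t50**2 + 0.01)
    t73 = t71*t72
    t74 = 1/(t39**2 + t47**2 + t49**2 + 0.01)
    t75 = kk*t74
    t76 = ey + t15
    t77 = ez + t2
    t78 = -t77
    t79 = -t10*t78 + t61*t76
    t80 = t4*t61
    t81 = t10*t62
    t82 = -t81
    t83 = t80 + t82
    t84 = t1*t66 - t10*t83
    t85 = -t60
    t86 = -t68
    t87 = t33*t53
    t88 = t36*t54
    t89 = -t88
    t90 = t87 + t89
    t91 = t30*t58 - t36*t90
    t92 = t84*t85 - t86*t91
    t93 = -t79
    t94 = t30*t59 - t53*t90
    t95 = -t94
    t96 = -t1*t78 - t12
    t97 = t1*t67 - t61*t83
    t98 = t60*t97 - t68*t94
    t99 = -t63 + t64
    t100 = t1*t76 + t99
    t101 = -t52*t94 + t69*t97
    t102 = -t97
    t103 = 1/(t52**2 + t68**2 + t97**2 + 0.01)
    t104 = t101**2 + t92**2 + t98**2
    t105 = t103*t104
    t106 = 1/(t60**2 + t69**2 + t94**2 + 0.01)
    t107 = kk*t103*t106
    t108 = ex + t6
    t109 = -t108
    t110 = t1*t109 - t10*t77
    t111 = -t109*t61 - t99
    t112 = -t80 + t81
    t113 = t112 + t61*t77
    t114 = -t76
    t115 = t1*t108 - t114*t61
    t116 = -t115
    t117 = t10*t114 + t112
    t118 = -t117
    t119 = t0*t3 - t108*t9 - t7*t9
    t120 = fy + t22
    t121 = fz + t31
    t122 = -t121
    t123 = t120*t53 - t122*t36
    t124 = -t123
    t125 = 2*t63 + t65
    t126 = -t10*t3 + t61*t62
    t127 = -t126
    t128 = -t55 + t56
    t129 = t120*t30 + t128
    t130 = t1*t3 + t11 - t5
    t131 = t122*t30 + t38
    t132 = t104*t106
    t133 = fx + t25
    t134 = 2*t14 + t17
    t135 = -t121*t20 - t46
    t136 = t1*t7 - t10*t4
    t137 = -t133
    t138 = -t121*t36 + t137*t30
    t139 = t128 + t137*t53
    t140 = -t139
    t141 = t61*t7 + t66
    t142 = -t141
    t143 = -t87 + t88
    t144 = -2*t11 + t5
    t145 = -t120
    t146 = t133*t30 - t145*t53
    t147 = t1*t8 - t16*t61
    t148 = -t133*t29 + t21*t32 - t26*t29
    t149 = -t147
    t150 = -t146
    t151 = t143 + t145*t36
    t152 = -t151
    t153 = t10*t16 + t83
    t154 = -t153
    t155 = -t32*t36 + t53*t54
    t156 = -t155
    t157 = 2*t55 + t57
    t158 = t30*t32 - t34 + t37
    t159 = 2*t44 + t45
    t160 = t26*t53 + t58
    t161 = t26*t30 - t33*t36
    t162 = -t160
    t163 = t34 - 2*t35*t36
    t164 = -t23*t53 + t30*t35
    t165 = t23*t36 + t90
    t166 = -t163
    t167 = -t165
    t168 = t60*t9
    t169 = -t10**2 + t13*t61
    t170 = t13*t60
    t171 = t9*t97
    t172 = t0*t13
    t173 = t72*t75
    t174 = t13*t9
    t175 = t0**2 + t9**2
    t176 = t0*t69
    t177 = t10*t95
    t178 = t0*t1 - t61**2
    t179 = -t178
    t180 = t20*t68
    t181 = t20*t53 - t36**2
    t182 = t21*t29
    t183 = t20*t21
    t184 = t71*t74
    t185 = t21*t52
    t186 = t21**2
    t187 = t186 + t29**2
    t188 = t20*t29
    t189 = t21*t30 - t53**2
    return (math.atan2(math.sqrt(t71 + 1.0e-12), t19*t47 + t39*t43 + t49*t50 + 1.0e-9),
            (1/2)*t73*t75,
            -t107*(t101*(-t100*t95 + t91*t96) + t105*(t100*t84 + t102*t96 + t86*t93) + t92*(t60*(-t0*t76 - t42) - t69*t79) + t98*(-t85*t96 + t93*t95)),
            t107*(-t101*(t69*(-t13*t77 - t18) + t94*(t0*t108 + t77*t9)) - t105*(t102*t113 + t110*t84 + t111*t86) + t92*(t110*t85 - t111*t91) - t98*(t111*t95 - t113*t85)),
            t107*(-t101*(t116*t91 - t118*t95) - t105*(t102*t116 + t118*t84 + t86*(t10*t108 + t12)) - t92*(-t117*t60 + t119*t69) + t98*(t115*t60 + t119*t94)),
            t107*(t101*(t130*t69 - t131*t52 - t94*(2*t40 + t41) + t97*(-t120*t21 - t28)) - t105*(-t102*t130 + t125*t84 + t127*t86) - t132*(t124*t85 + t129*t91 - t131*t95) + t92*(t124*t84 + t125*t85 - t127*t91 - t129*t86) + t98*(t123*t97 - t126*t94 + t130*t60 - t131*t68)),
            t107*(t101*(-t134*t69 + t135*t52 + t94*(t0*t7 + t3*t9) + t97*(t121*t29 + t133*t21)) - t105*(t102*(2*t80 + t82) + t136*t84 + t142*t86) - t132*(t138*t91 + t140*t85 + t95*(t121*t53 + t143)) + t92*(t136*t85 - t138*t86 + t140*t84 - t142*t91) + t98*(-t134*t60 + t135*t68 + t139*t97 - t141*t94)),
            t107*(-t101*(t102*t152 + t149*t91 - t150*t84 - t154*t95) - t105*(t102*t149 - t144*t86 + t154*t84) - t132*(t150*t95 + t152*t91 + t85*(t133*t36 + t38)) - t92*(-t144*t69 - t148*t52 + t151*t68 - t153*t60) + t98*(-t144*t94 - t146*t68 + t147*t60 - t148*t97)),
            t107*(t101*(-t158*t52 + t97*(2*t24 + t27)) - t132*(t156*t85 + t157*t91 - t158*t95) + t92*(t156*t84 - t157*t86) + t98*(t155*t97 - t158*t68)),
            t107*(t101*(t159*t52 - t97*(t21*t26 + t29*t32)) - t132*(t161*t91 + t162*t85 + t95*(2*t87 + t89)) + t92*(-t161*t86 + t162*t84) + t98*(t159*t68 + t160*t97)),
            t107*(-t101*(t164*t52 + t165*t97) - t132*(-t164*t95 + t166*t85 + t167*t91) + t92*(t166*t84 - t167*t86) + t98*(t163*t97 - t164*t68)),
            t173*(t0*t51*(t13*t47 - t49*t9) - t48*(-t0*t168 + t169*t94) + t70*(t0*t170 + t169*t69) - t73*(t0*t171 + t169*t68 - t172*t52)),
            t173*(-t13*t48*(t0*t94 - t168) - t51*(-t174*t69 + t175*t94) + t70*(t13*t176 - t175*t60) - t73*(t13*t171 + t172*t68 + t175*t52)),
            -t173*(t101*(t177*t61 + t179*t91) + t73*(t0*t68*t9 - t174*t52 + t178*t97) - t9*t92*(t170 + t176) + t98*(t0*t177 - t179*t85)),
            -t173*(t101*t30*(t102*t20 + t36*t84) + t184*(t181*t60 + t182*t94 - t183*t69) + t92*(t180*t21 + t181*t52) - t98*(t181*t97 - t182*t68)),
            -t173*(-t101*(t187*t97 - t188*t52) + t184*(t183*t60 + t187*t69 + t188*t94) + t53*t98*(t102*t30 + t29*t86) + t92*(t185*t20 - t187*t68)),
            t173*(-t184*(t182*t60 - t188*t69 + t189*t94) - t29*t70*(t180 + t185) + t48*(t182*t19 - t43*(t186 + t20**2)) - t51*(t188*t97 + t189*t52)))



def dih_long_axis_term(ax, ay, az, bx, by, bz, cx, cy, cz, ox, oy, oz, ux, uy, uz, kk):
    """Signed longitudinal dihedral for (A, B, C), radial reference from the tube axis (origin o, unit direction u)."""
    t0 = ax - bx
    t1 = ay - by
    t2 = az - bz
    t3 = ax - ox
    t4 = ay - oy
    t5 = az - oz
    t6 = t3*ux + t4*uy + t5*uz
    t7 = t6*ux
    t8 = -ax + ox + t7
    t9 = -t8
    t10 = t6*uy
    t11 = -ay + oy + t10
    t12 = -t11
    t13 = t6*uz
    t14 = -az + oz + t13
    t15 = -t14
    t16 = t12**2 + t15**2 + t9**2 + 1.0e-12
    t17 = 1/math.sqrt(t16)
    t18 = -t0
    t19 = -cy
    t20 = by + t19
    t21 = -t20
    t22 = -t1
    t23 = -cx
    t24 = bx + t23
    t25 = -t24
    t26 = t18*t21 - t22*t25
    t27 = t15*t22
    t28 = -t2
    t29 = t12*t28
    t30 = t27 - t29
    t31 = -cz
    t32 = bz + t31
    t33 = -t32
    t34 = -t21*t28 + t22*t33
    t35 = t12*t18
    t36 = t22*t9
    t37 = t35 - t36
    t38 = t26*t30 - t34*t37
    t39 = t0*t11
    t40 = -t1*t8 + t39
    t41 = t18*t33 - t25*t28
    t42 = t11**2 + t14**2 + t8**2 + 1.0e-12
    t43 = 1/math.sqrt(t42)
    t44 = t41*t43
    t45 = t0*t20 - t1*t24
    t46 = t15*t18
    t47 = t28*t9
    t48 = t46 - t47
    t49 = t17*t48
    t50 = t40*t44 - t45*t49
    t51 = t0*t50
    t52 = t1*t14
    t53 = -t11*t2 + t52
    t54 = t1*t32 - t2*t20
    t55 = -t17*t48*t54 + t44*t53
    t56 = -t55
    t57 = t2*t56
    t58 = t40*t43
    t59 = t0*t32 - t2*t24
    t60 = t2*t8
    t61 = t0*t14 - t60
    t62 = t43*t53
    t63 = t45**2 + t54**2 + 0.01
    t64 = 1/(t59**2 + t63)
    t65 = 1/t42
    t66 = t40*t59 - t45*t61
    t67 = -t40*t54 + t45*t53
    t68 = t55**2 + t65*t66**2 + t65*t67**2
    t69 = t64*t68
    t70 = t40**2*t65 + t53**2*t65 + 0.01
    t71 = 1/(t61**2*t65 + t70)
    t72 = kk*t71
    t73 = -t41
    t74 = 1/(t41**2 + t63)
    t75 = 1/t16
    t76 = t38**2*t75 + t50**2 + t56**2
    t77 = t74*t76
    t78 = ux*uy
    t79 = t28*t78
    t80 = ux*uz
    t81 = t22*t80
    t82 = ux**2 - 1
    t83 = -t82
    t84 = t75*(t12*t78 + t15*t80 - t83*t9)
    t85 = t27*t84 - t29*t84 + t79 - t81
    t86 = -t10 + t4
    t87 = t18*t78 + t22*t83 - t35*t84 + t36*t84 + t86
    t88 = -t87
    t89 = t1*t80
    t90 = t11*t78 + t14*t80 + t8*t82
    t91 = t65*t90
    t92 = t0*t14*t65*t90 - t0*t80 - t14 + t2*t82 - t60*t91
    t93 = t20*t49
    t94 = -t48
    t95 = -t13 + t5
    t96 = 1/(t48**2*t75 + t70)
    t97 = t75*t76*t96
    t98 = kk*t74*t96
    t99 = uy**2 - 1
    t100 = -t99
    t101 = uy*uz
    t102 = -t100*t12 + t101*t15 + t78*t9
    t103 = t102*t75
    t104 = -t100*t28 - t101*t22 + t102*t15*t22*t75 - t103*t29 - t95
    t105 = t3 - t7
    t106 = t100*t18 + t103*t35 - t103*t36 + t105 + t22*t78
    t107 = -t101*t18
    t108 = t103*t46 - t103*t47 + t107 + t79
    t109 = -t108
    t110 = t101*t14 + t11*t99 + t78*t8
    t111 = uz**2 - 1
    t112 = t101*t11 + t111*t14 + t8*t80
    t113 = t112*t65
    t114 = t1*t111 - t101*t2 + t11*t112*t2*t65 - t11 - t113*t52
    t115 = t17*t38
    t116 = -t111
    t117 = t75*(t101*t12 - t116*t15 + t80*t9)
    t118 = t107 + t117*t35 - t117*t36 + t81
    t119 = t105 + t116*t18 + t117*t46 - t117*t47 + t28*t80
    t120 = -t119
    t121 = t17*t50
    t122 = ay + t19
    t123 = -t122
    t124 = az + t31
    t125 = t12*t73
    t126 = ax + t23
    t127 = -t126
    t128 = t1*t49
    return (math.atan2((t1*t17*t38 - t51 - t57)/math.sqrt(t0**2 + t1**2 + t2**2 + 1.0e-12), t43*t59*t61 + t45*t58 + t54*t62 + 1.0e-9),
            (1/2)*t69*t72,
            t98*(t38*t75*(t20*t30 + t26*t85 - t34*t88) - t43*t56*(t32*t53 + t41*(t11*t2*t65*t90 - t2*t78 - t52*t91 + t89) + t54*t92) + t50*(-t17*t41*t87 + t32*t40*t43 + t43*t45*t92 - t93) - t77*(t20*t26 + t33*t73) - t97*(t30*t85 + t37*t88 + t94*(t18*t80 + t28*t83 - t46*t84 + t47*t84 + t95))),
            t98*(-t17*t56*(-t104*t73 + t109*t34 + t32*t94) + t38*t75*(t104*t26 - t106*t34 + t25*t30 - t32*t37) + t50*(-t108*t17*t45 + t24*t49 + t44*(t0*t99 + t1*t110*t65*t8 - t1*t78 - t110*t39*t65 - t8)) - t77*(t25*t26 + t32*t34) - t97*(t104*t30 + t106*t37 + t109*t94)),
            t98*(-t115*t43*(-t114*t45 - t20*t40 + t54*(t0*uy*uz + t1*t112*t65*t8 - t113*t39 - t89)) - t121*(t118*t73 - t120*t26 + t24*t37) + t56*(-t114*t44 + t119*t17*t54 + t24*t62 - t93) - t77*(t21*t34 + t24*t73) - t97*(t118*t37 + t120*t94 + t30*(t101*t28 + t116*t22 + t117*t27 - t117*t29 + t86))),
            t98*(-t121*(-t123*t94 + t124*t37 + t125 + t15*t26) + t38*t75*(-t12*t34 + t123*t30) + t43*t56*(t124*t53 - t14*t54) - t77*(t123*t26 + t124*t73) - t97*(t12*t37 - t15*t94)),
            t64*t72*(-t43*t66*(t126*t49 - t44*t8) + t55*(t124*t49 - t14*t44) + t65*t67*(t124*t40 + t126*t53 - t14*t45 - t54*t8) - t65*t68*t71*(-t14*t53 + t40*t8) - t69*(-t124*t54 + t126*t45)),
            -t98*(t17*(t38*t43*(-t11*t45 + t122*t40) + t50*(t127*t37 - t26*t9) + t56*(t122*t94 + t125 - t127*t30 + t34*t9)) + t77*(t122*t34 + t127*t73) + t97*(-t12*t30 + t9*t94)),
            t98*(t1*t115*t62 + t50*(-t128 + t2*t40*t43) - t57*t62 - t77*(t1*t26 + t28*t73)),
            t98*(t38*t75*(t18*t30 - t2*t37) + t49*t51 + t49*t57 - t77*(t18*t26 + t2*t34)),
            t98*(t1*t17*t38*t40*t43 - t51*t58 + t56*(t0*t62 - t128) - t77*(t0*t73 + t22*t34)))



def dih_lat_axis_term(dx, dy, dz, ex, ey, ez, fx, fy, fz, ox, oy, oz, ux, uy, uz, kk):
    """Unsigned lateral dihedral for (D, E, F), radial references from the tube axis (origin o, unit direction u)."""
    t0 = -ex
    t1 = dx + t0
    t2 = -ox
    t3 = dx + t2
    t4 = -oy
    t5 = dy + t4
    t6 = -oz
    t7 = dz + t6
    t8 = t3*ux + t5*uy + t7*uz
    t9 = t8*uy
    t10 = -dy + oy + t9
    t11 = -ey
    t12 = dy + t11
    t13 = t8*ux
    t14 = -dx + ox + t13
    t15 = t12*t14
    t16 = t1*t10 - t15
    t17 = ey - fy
    t18 = -ez
    t19 = ex + t2
    t20 = ey + t4
    t21 = ez + t6
    t22 = t19*ux + t20*uy + t21*uz
    t23 = t22*uz
    t24 = oz + t18 + t23
    t25 = ez - fz
    t26 = t22*uy
    t27 = oy + t11 + t26
    t28 = t25*t27
    t29 = t17*t24 - t28
    t30 = t8*uz
    t31 = -dz + oz + t30
    t32 = dz + t18
    t33 = t10*t32
    t34 = t12*t31 - t33
    t35 = ex - fx
    t36 = t22*ux
    t37 = ox + t0 + t36
    t38 = t17*t37
    t39 = t27*t35 - t38
    t40 = t16*t29 - t34*t39
    t41 = t10**2 + t14**2 + t31**2 + 1.0e-12
    t42 = 1/t41
    t43 = t24**2 + t27**2 + t37**2 + 1.0e-12
    t44 = 1/t43
    t45 = t42*t44
    t46 = t24*t35
    t47 = -t25*t37 + t46
    t48 = 1/math.sqrt(t43)
    t49 = t47*t48
    t50 = -t1
    t51 = -t10
    t52 = t50*t51
    t53 = -t12
    t54 = -t14
    t55 = t53*t54
    t56 = t52 - t55
    t57 = -t31
    t58 = t51**2 + t54**2 + t57**2 + 1.0e-12
    t59 = 1/math.sqrt(t58)
    t60 = t56*t59
    t61 = t1*t31
    t62 = -t14*t32 + t61
    t63 = -t35
    t64 = -t27
    t65 = t63*t64
    t66 = -t17
    t67 = -t37
    t68 = t66*t67
    t69 = t65 - t68
    t70 = 1/math.sqrt(t41)
    t71 = -t24
    t72 = t64**2 + t67**2 + t71**2 + 1.0e-12
    t73 = 1/math.sqrt(t72)
    t74 = -t49*t60 + t62*t69*t70*t73
    t75 = t66*t71
    t76 = -t25
    t77 = t64*t76
    t78 = t75 - t77
    t79 = t73*t78
    t80 = t62*t70
    t81 = t53*t57
    t82 = -t32
    t83 = t51*t82
    t84 = t81 - t83
    t85 = t47*t48*t59*t84 - t79*t80
    t86 = t40**2*t45 + t74**2 + t85**2
    t87 = t48*t70
    t88 = t42*t62**2 + 0.01
    t89 = 1/(t16**2*t42 + t34**2*t42 + t88)
    t90 = t86*t89
    t91 = t44*t47**2 + 0.01
    t92 = 1/(t29**2*t44 + t39**2*t44 + t91)
    t93 = kk*t92
    t94 = -t69
    t95 = ux*uy
    t96 = ux*uz
    t97 = t53*t96
    t98 = 1/t58
    t99 = ux**2 - 1
    t100 = -t99
    t101 = t98*(-t100*t54 + t51*t95 + t57*t96)
    t102 = t101*t81 - t101*t83 + t82*t95 - t97
    t103 = -t78
    t104 = t5 - t9
    t105 = t56*t78 - t69*t84
    t106 = 1/t72
    t107 = t106*t98
    t108 = t105*t107
    t109 = t50*t57
    t110 = t54*t82
    t111 = t109 - t110
    t112 = -t84
    t113 = t63*t71
    t114 = t67*t76
    t115 = t113 - t114
    t116 = t103*t111 - t112*t115
    t117 = -t30 + t7
    t118 = t100*t82 - t101*t109 + t101*t110 + t117 + t50*t96
    t119 = t10*t95 + t14*t99 + t31*t96
    t120 = t70*(t1*t10*t119*t42 - t1*t95 - t10 - t119*t15*t42 + t12*t99)
    t121 = t69*t73
    t122 = t118*t59
    t123 = -t56
    t124 = -t111*t94 + t115*t123
    t125 = t59*t73
    t126 = t124*t125
    t127 = t89*t93
    t128 = uy**2 - 1
    t129 = -t128
    t130 = uy*uz
    t131 = t98*(-t129*t51 + t130*t57 + t54*t95)
    t132 = t129*t50 - t13 + t131*t52 - t131*t55 + t3 + t53*t95
    t133 = t10*t128 + t130*t31 + t14*t95
    t134 = t133*t42
    t135 = t1*uy*uz + t133*t14*t32*t42 - t134*t61 - t32*t95
    t136 = -t12*t130 + t12*t133*t31*t42 + t128*t32 - t134*t33 - t31
    t137 = t116*t125
    t138 = t121*t70
    t139 = t42*t62
    t140 = t56*t98
    t141 = t59*t84
    t142 = t141*t70
    t143 = uz**2 - 1
    t144 = -t143
    t145 = t98*(t130*t51 - t144*t57 + t54*t96)
    t146 = -t130*t50 + t145*t52 - t145*t55 + t97
    t147 = t104 + t130*t82 + t144*t53 + t145*t81 - t145*t83
    t148 = t10*t130 + t14*t96 + t143*t31
    t149 = t1*t143 + t14*t148*t32*t42 - t14 - t148*t42*t61 - t32*t96
    t150 = t76*t95
    t151 = t66*t96
    t152 = t106*(-t100*t67 + t64*t95 + t71*t96)
    t153 = t150 - t151 + t152*t75 - t152*t77
    t154 = -t153
    t155 = t20 - t26
    t156 = t21 - t23
    t157 = t100*t76 - t113*t152 + t114*t152 + t156 + t63*t96
    t158 = t10*t49*t70
    t159 = -t31*t69*t70*t73
    t160 = t24*t96 + t27*t95 + t37*t99
    t161 = t160*t27*t35*t44 - t160*t38*t44 + t17*t99 - t27 - t35*t95
    t162 = t157*t73
    t163 = t86*t92
    t164 = -t130*t63
    t165 = -t129*t64 + t130*t71 + t67*t95
    t166 = t106*t165
    t167 = t113*t166 - t114*t166 + t150 + t164
    t168 = t129*t76 + t130*t66 + t156 - t166*t75 + t166*t77
    t169 = t19 - t36
    t170 = -t106*t165*t66*t67 + t129*t63 + t166*t65 + t169 + t66*t95
    t171 = -t170
    t172 = t107*t124
    t173 = 1/(t56**2*t98 + t84**2*t98 + t88)
    t174 = t105**2 + t116**2 + t124**2
    t175 = t128*t27 + t130*t24 + t37*t95
    t176 = 1/(t106*t69**2 + t106*t78**2 + t91)
    t177 = t174*t176*t98/t72**2
    t178 = kk*t173*t176
    t179 = t106*(t130*t64 - t144*t71 + t67*t96)
    t180 = t151 + t164 + t179*t65 - t179*t68
    t181 = -t180
    t182 = t130*t76 + t144*t66 + t155 + t179*t75 - t179*t77
    t183 = t130*t27 + t143*t24 + t37*t96
    t184 = t143*t35 + t183*t25*t37*t44 - t183*t44*t46 - t25*t96 - t37
    t185 = t44*t47
    t186 = t27*t40*t45
    t187 = t48*t85
    t188 = t27*t80
    t189 = t48*t74
    t190 = t48*t80
    return (math.atan2(math.sqrt(t86 + 1.0e-12), t16*t39*t87 + t29*t34*t87 + t49*t80 + 1.0e-9),
            (1/2)*t90*t93,
            -t127*(t108*(-t102*t94 - t103*(t100*t53 - t101*t52 + t101*t55 + t104 + t50*t95)) - t116*t73*t98*(t102*t49 + t118*t79) + t126*(-t120*t49 + t121*t122) + t90*(t102*t84*t98 - t120*t60 - t122*t80)),
            -t127*(t108*(t103*t132 + t94*(t117 + t129*t82 + t130*t53 - t131*t81 + t131*t83)) + t126*(t132*t47*t48*t59 - t135*t138) + t137*t70*(t135*t79 + t136*t49) + t90*(t132*t140 + t135*t139 - t136*t142)),
            -t127*(t108*(t103*t146 - t147*t94) + t126*(-t138*t149 + t146*t47*t48*t59) + t137*(-t147*t49*t59 + t149*t70*t73*t78) + t90*(t139*t149 + t140*t146 + t147*t84*t98)),
            t127*(t106*t116*t98*(t103*t57 + t111*t154 + t112*t157) - t108*(t103*t51 + t112*(t100*t66 - t152*t65 + t152*t68 + t155 + t63*t95) - t123*t154) - t126*(-t158 - t159 + t161*t48*t62*t70 - t162*t60) - t163*(t106*t153*t78 - t121*t161*t48 - t162*t49) + t42*t86*t89*(t10*t16 + t31*t62)),
            t178*(t105*t125*(t14*t70*t73*t78 - t141*t170*t73 - t159 - t48*t60*(t128*t25 - t130*t17 + t17*t175*t24*t44 - t175*t28*t44 - t24)) - t106*t173*t174*(-t112*t57 + t123*t54)/t58**2 + t107*t116*(t111*t168 - t112*t167 + t115*t57) + t172*(-t111*t171 + t115*t54 + t123*t167) - t177*(t103*t168 + t115*t167 + t171*t94)),
            -t127*(t108*(t112*t181 + t123*t182 + t51*t94) + t137*(t14*t70*t79 - t141*t184*t48 - t158 + t182*t73*t80) + t163*(t106*t180*t69 + t106*t182*t78 + t184*t185) - t172*(-t111*t181 + t123*(t113*t179 - t114*t179 + t144*t63 + t169 + t76*t96) + t54*t94) + t90*(t10*t142 + t139*t14)),
            t127*(t163*t44*(t24*t47 + t27*t39) + t186*t34 - t187*t24*t34*t70 + t189*(-t188 + t24*t60)),
            t178*(-t108*(t112*t67 + t123*t71) + t126*t190*t37 + t137*t190*t24 - t177*(-t103*t71 + t67*t94)),
            t127*(t16*t186 - t16*t189*t37*t70 - t163*(t185*t37 + t27*t48*t79) + t187*(-t188 + t37*t59*t84)))

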